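fingerprint,description
SubFPC1,Primary Carbon
SubFPC2,Secondary Carbon
SubFPC3,Tertiary Carbon
SubFPC4,Quaternary Carbon
SubFPC5,Alkene
SubFPC12,Alcohol
SubFPC16,Dialkylether
SubFPC18,Alkylarylether
SubFPC26,Tertiary Aliphalitic Amine
SubFPC28,Primary Aromatic Amine
SubFPC32,Secondary Mixed Amine
SubFPC33,Tertiary Mixed Amine
SubFPC88,Carboxylic Acid derivative
SubFPC99,Primary Amide
SubFPC100,Secondary Amide
SubFPC101,Tertiary Amide
SubFPC133,Nitrile
SubFPC137,Vinylogous Ester
SubFPC143,Carbonic Acid Derivatives
SubFPC171,Arylchloride
SubFPC172,Arylfluoride
SubFPC179,Hetero N basic H
SubFPC180,Hetero N basic no H
SubFPC184,Heteroaromatic
SubFPC200,Sulfon
SubFPC214,Sulfonic Derivative
SubFPC279,Annelated Rings
SubFPC287,Spiro
SubFPC294,Trifluoromethyl
SubFPC295,C ONS Bond
SubFPC301,"1,5-Tautomerizable"
SubFPC302,Rotatable Bond
SubFPC307,Chiral Center Specified
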
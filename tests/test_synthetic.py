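"""The synthetic generators: determinism, planted structure, ground truth."""

import numpy as np
import pytest

from fpqsar import clustering, synthetic
from fpqsar.synthetic import SyntheticSpec


def test_matrix_is_reproducible_and_integer():
    spec = SyntheticSpec(n_compounds=10, n_features=4, seed=1)
    a = synthetic.generate_fingerprint_matrix(spec)
    b = synthetic.generate_fingerprint_matrix(spec)
    assert np.array_equal(a.values, b.values)
    assert a.values.shape == (10, 4)
    assert np.issubdtype(a.values.dtype, np.integer)
    assert (a.values >= 0).all() and (a.values <= spec.count_cap).all()
    assert a.ids[0] == "SYN000001"


def test_collinear_block_achieves_target_correlation():
    spec = SyntheticSpec(
        n_compounds=500, n_features=5, collinear_blocks=[(0, 1, 0.95)], seed=3
    )
    X = synthetic.generate_fingerprint_matrix(spec)
    r = np.corrcoef(X.values[:, 0], X.values[:, 4])[0, 1]
    assert abs(r) >= 0.9


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_compounds=0, n_features=4),
        dict(n_compounds=10, n_features=0),
        dict(n_compounds=10, n_features=4, informative_idx=[7], coefficients=[1.0]),
        dict(n_compounds=10, n_features=4,
             collinear_blocks=[(0, 1, 0.9), (0, 1, 0.9)]),  # duplicate source
        dict(n_compounds=10, n_features=4, noise_sd=-0.1),
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(ValueError):
        SyntheticSpec(seed=1, **kwargs)


class TestActivity:
    def test_noiseless_single_feature_identity(self):
        spec = SyntheticSpec(
            n_compounds=50, n_features=3, informative_idx=[0],
            coefficients=[1.0], noise_sd=0.0, seed=5,
        )
        X = synthetic.generate_fingerprint_matrix(spec)
        y = synthetic.generate_activity(X, spec, intercept=0.0)
        assert np.allclose(y, X.values[:, 0])

    def test_mean_anchored_near_default(self):
        spec = SyntheticSpec(
            n_compounds=400, n_features=10, informative_idx=[0, 1],
            coefficients=[0.5, 0.5], noise_sd=0.3, seed=6,
        )
        X = synthetic.generate_fingerprint_matrix(spec)
        y = synthetic.generate_activity(X, spec)
        assert abs(y.mean() - 6.5) < 0.1

    def test_variance_decomposition_matches_analytic_r2(self):
        """Sample R2 between y and the noiseless signal ~ V/(V + sd^2)."""
        spec = SyntheticSpec(
            n_compounds=1000, n_features=10, informative_idx=[0, 1, 2],
            coefficients=[0.5, 0.4, 0.3], noise_sd=0.5, seed=7,
        )
        X = synthetic.generate_fingerprint_matrix(spec)
        y = synthetic.generate_activity(X, spec)
        signal = X.values[:, :3].astype(float) @ np.array([0.5, 0.4, 0.3])
        v = signal.var()
        expected = v / (v + 0.25)
        r = np.corrcoef(y, signal)[0, 1]
        assert r * r == pytest.approx(expected, abs=0.05)

    def test_null_signal_has_no_dependence(self):
        spec = SyntheticSpec(
            n_compounds=300, n_features=5, informative_idx=[], coefficients=[],
            noise_sd=1.0, seed=8,
        )
        X = synthetic.generate_fingerprint_matrix(spec)
        y = synthetic.generate_activity(X, spec)
        for j in range(5):
            assert abs(np.corrcoef(y, X.values[:, j])[0, 1]) < 0.15

    def test_noise_sd_solver_hits_target(self):
        spec = SyntheticSpec(
            n_compounds=2000, n_features=10, informative_idx=[0, 1],
            coefficients=[0.5, 0.5], noise_sd=0.0, seed=9,
        )
        X = synthetic.generate_fingerprint_matrix(spec)
        spec.noise_sd = synthetic.noise_sd_for_r2(X, spec, 0.8)
        y = synthetic.generate_activity(X, spec)
        signal = X.values[:, :2].astype(float) @ np.array([0.5, 0.5])
        assert np.corrcoef(y, signal)[0, 1] ** 2 == pytest.approx(0.8, abs=0.05)


class TestRawRecords:
    def test_clean_records_all_survive(self):
        recs, truth = synthetic.generate_raw_records(100, seed=1, fractions={})
        assert len(recs) == 100
        assert truth["n_survivors"] == 100
        assert (recs["standard_type"] == "IC50").all()

    def test_exact_qualifier_count(self):
        recs, _ = synthetic.generate_raw_records(
            100, seed=2, fractions={"qualifier": 0.2}
        )
        assert recs["relation"].isin([">", "<"]).sum() == 20

    def test_duplicate_structure(self):
        recs, truth = synthetic.generate_raw_records(
            50, seed=3, fractions={"duplicate": 0.2}
        )
        assert len(recs) == 50
        assert truth["n_unique_compounds"] == 40
        assert recs["compound_id"].nunique() == 40

    def test_determinism(self):
        a, _ = synthetic.generate_raw_records(80, seed=4, fractions={"missing": 0.1})
        b, _ = synthetic.generate_raw_records(80, seed=4, fractions={"missing": 0.1})
        assert a.equals(b)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_raw_records(10, seed=0, fractions={"missing": -0.1})

    def test_oversubscribed_fractions_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_raw_records(
                10, seed=0, fractions={"missing": 0.7, "qualifier": 0.7}
            )


class TestClusteredFingerprints:
    def test_planted_similarities_hold(self):
        m, labels = synthetic.generate_clustered_fingerprints(
            [(10, 0.9), (8, 0.9)], n_singletons=3, seed=5
        )
        sim = clustering.pairwise_tanimoto(m.values)
        for cid, (size, target) in enumerate([(10, 0.9), (8, 0.9)]):
            members = np.flatnonzero(labels == cid)
            block = sim[np.ix_(members, members)]
            assert block[~np.eye(size, dtype=bool)].min() >= target
        cross = labels[:, None] != labels[None, :]
        assert sim[cross].max() < 0.8

    def test_single_member_cluster(self):
        m, labels = synthetic.generate_clustered_fingerprints([(1, 1.0)], 0, seed=6)
        assert m.values.shape[0] == 1 and labels.tolist() == [0]

    def test_all_singletons(self):
        m, labels = synthetic.generate_clustered_fingerprints([], 10, seed=7)
        assert (labels == -1).all()
        sim = clustering.pairwise_tanimoto(m.values)
        assert sim[~np.eye(10, dtype=bool)].max() == 0.0

    def test_low_similarity_target_warns(self):
        with pytest.warns(UserWarning, match="not be recoverable"):
            synthetic.generate_clustered_fingerprints([(5, 0.5)], 0, seed=8)

    def test_potency_offsets_planted(self):
        _, labels, compounds = synthetic.generate_clustered_dataset(
            [(30, 0.9), (25, 0.9)], 4, seed=9, potency_offsets=[2.0, 0.5]
        )
        base = compounds.loc[labels == -1, "pIC50"].mean()
        c0 = compounds.loc[labels == 0, "pIC50"].mean()
        c1 = compounds.loc[labels == 1, "pIC50"].mean()
        assert c0 - base == pytest.approx(2.0, abs=0.4)
        assert c1 - base == pytest.approx(0.5, abs=0.4)


def test_writers_round_trip(tmp_path):
    recs, truth = synthetic.generate_raw_records(20, seed=1, fractions={})
    synthetic.write_bioactivity_csv(recs, tmp_path / "bio.csv")
    synthetic.write_ground_truth_json(truth, tmp_path / "truth.json")
    import json

    import pandas as pd

    back = pd.read_csv(tmp_path / "bio.csv")
    assert back["compound_id"].tolist() == recs["compound_id"].tolist()
    loaded = json.loads((tmp_path / "truth.json").read_text())
    assert loaded["n_survivors"] == truth["n_survivors"]
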
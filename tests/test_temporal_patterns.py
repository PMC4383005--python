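"""Baseline subtraction, pattern grammar, k-means and cluster classification."""

import numpy as np
import pandas as pd
import pytest

from stagewise import (
    DEFAULT_DESIGN,
    ExpressionMatrix,
    PatternCode,
    SimConfig,
    classify_clusters,
    classify_genes_directly,
    default_pattern_set,
    kmeans_cluster,
    match_pattern,
    simulate_expression,
    subtract_baseline,
    transition_diffs,
)
from stagewise.design import StageDesign
from stagewise.matrix import meta_from_design
from stagewise.synthetic_data import PatternPlant

from conftest import make_matrix, trajectory_rows


class TestSubtractBaseline:
    def test_shifts_by_es_level(self):
        em = make_matrix(trajectory_rows({"g": [4, 6, 4, 4, 4, 4]}))
        d = subtract_baseline(em)
        assert d.values.loc["g", "ES:unsorted"] == 0
        assert d.values.loc["g", "NE:HES5+"] == 2

    def test_idempotent(self):
        em = make_matrix(trajectory_rows({"g": [4, 6, 5, 4, 3, 4]}))
        once = subtract_baseline(em)
        twice = subtract_baseline(once)
        pd.testing.assert_frame_equal(twice.values, once.values)

    def test_two_baseline_samples_without_designation_error(self):
        design = StageDesign(stages=("ES", "NE"),
                             populations={"ES": frozenset({"HES5+", "HES5-"}),
                                          "NE": frozenset({"HES5+", "HES5-"})})
        sids = design.all_sample_ids()
        em = ExpressionMatrix(pd.DataFrame([[1.0] * 4], index=["g"], columns=sids),
                              meta_from_design(design, sids))
        with pytest.raises(ValueError, match="designate"):
            subtract_baseline(em, design=design)
        # designating one resolves it
        d = subtract_baseline(em, design=design, baseline_sample="ES:HES5+")
        assert (d.values.loc["g"] == 0).all()


class TestPatternGrammar:
    def test_default_design_yields_the_eight_codes(self):
        codes = {p.code for p in default_pattern_set()}
        assert codes == {"UFFFF", "UDFFF", "FUFFF", "FUDFF",
                         "FFUFF", "FFUDF", "FFFUF", "FFFFU"}

    def test_two_stage_design_yields_single_onset(self):
        codes = [p.code for p in default_pattern_set(StageDesign(stages=("ES", "NE")))]
        assert codes == ["U"]

    def test_single_stage_design_errors(self):
        with pytest.raises(ValueError):
            default_pattern_set(StageDesign(stages=("ES",)))

    def test_codes_pairwise_mutually_exclusive(self):
        """No diff vector can satisfy two default codes: they disagree at a
        position where both are concrete and incompatible."""
        codes = [p.code for p in default_pattern_set()]
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                assert any(ca != cb for ca, cb in zip(a, b) if ca != "*" and cb != "*")
                # U vs D or U/D vs F at some shared position -> disjoint
                assert any({ca, cb} <= {"U", "F", "D"} and ca != cb
                           for ca, cb in zip(a, b))


class TestTransitionDiffsAndMatch:
    @pytest.mark.parametrize("traj,expected", [
        ([0, 2, 2, 2, 2, 2], [2, 0, 0, 0, 0]),
        ([1, 1, 1, 1, 1, 1], [0, 0, 0, 0, 0]),
        ([0, 1.5, 0.2, 0.2, 0.2, 0.2], [1.5, -1.3, 0, 0, 0]),
    ])
    def test_diffs(self, traj, expected):
        np.testing.assert_allclose(transition_diffs(traj), expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            transition_diffs([0, 1, 2])
        with pytest.raises(ValueError):
            match_pattern([1.0, 0.0], PatternCode("UFFFF"))

    @pytest.mark.parametrize("diffs,code,expected", [
        ([2, 0, 0, 0, 0], "UFFFF", True),
        ([2, 0, 0, 0, 0], "UDFFF", False),
        ([1.0, 0, 0, 0, 0], "UFFFF", True),  # inclusive >= theta
        ([0.999, 0, 0, 0, 0], "UFFFF", False),
        ([2, -1.0, 0, 0, 0], "UDFFF", True),
        ([0, 0, 0, 0, 0], "FFFFF", True),
        ([5, -5, 5, -5, 5], "*****", True),
    ])
    def test_match(self, diffs, code, expected):
        assert match_pattern(np.array(diffs, float), PatternCode(code)) is expected


class TestKMeans:
    def features(self, X):
        return pd.DataFrame(X, index=[f"g{i}" for i in range(len(X))])

    def test_k_equals_n_gives_singletons_zero_inertia(self):
        X = self.features(np.arange(12, dtype=float).reshape(4, 3))
        res = kmeans_cluster(X, k=4, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert res.assignment.nunique() == 4

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(-5, 0.1, size=(50, 3))
        b = rng.normal(5, 0.1, size=(50, 3))
        X = self.features(np.vstack([a, b]))
        res = kmeans_cluster(X, k=2, seed=0)
        labels = res.assignment.to_numpy()
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = self.features(rng.normal(size=(40, 5)))
        r1 = kmeans_cluster(X, k=5, seed=3)
        r2 = kmeans_cluster(X, k=5, seed=3)
        pd.testing.assert_series_equal(r1.assignment, r2.assignment)
        pd.testing.assert_frame_equal(r1.centroids, r2.centroids)

    def test_centroids_are_member_means(self):
        rng = np.random.default_rng(2)
        X = self.features(rng.normal(size=(60, 4)))
        res = kmeans_cluster(X, k=7, seed=0)
        for cid in res.centroids.index:
            members = X.loc[res.assignment[res.assignment == cid].index]
            np.testing.assert_allclose(res.centroids.loc[cid], members.mean(axis=0),
                                       atol=1e-9)

    def test_invalid_k_errors(self):
        X = self.features(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            kmeans_cluster(X, k=0)
        with pytest.raises(ValueError):
            kmeans_cluster(X, k=4)


def planted_delta(codes, n_per_code, amplitude=2.0, noise_sd=0.1, seed=0):
    cfg = SimConfig(
        n_background=0, noise_sd=noise_sd, seed=seed,
        planted_patterns=tuple(PatternPlant(c, n_per_code, amplitude) for c in codes))
    em, gt = simulate_expression(cfg)
    return subtract_baseline(em), gt


class TestClassifyClusters:
    def test_planted_codes_recovered(self):
        """Planted-pattern recovery: every classified gene gets its planted code
        and nearly all planted genes are classified."""
        delta, gt = planted_delta(["UFFFF", "FFUFF", "FFFFU"], 100)
        res = classify_clusters(delta, k=12, patterns=default_pattern_set(), seed=0)
        classified = res.gene_pattern.dropna()
        assert res.n_classified >= 285
        truth = gt.pattern.dropna()
        assert (classified == truth.loc[classified.index]).all()

    def test_pure_noise_yields_no_classifications(self):
        cfg = SimConfig(n_background=300, noise_sd=0.1, seed=0)
        em, _ = simulate_expression(cfg)
        delta = subtract_baseline(em)
        res = classify_clusters(delta, k=12, patterns=default_pattern_set(), seed=0)
        assert res.n_classified == 0

    def test_single_cluster_of_identical_trajectories(self):
        delta, _ = planted_delta(["UFFFF"], 20, noise_sd=0.0)
        res = classify_clusters(delta, k=1, patterns=default_pattern_set(), seed=0)
        assert res.n_classified == 20
        assert set(res.gene_pattern) == {"UFFFF"}

    def test_gene_inherits_cluster_pattern_and_counts_consistent(self):
        delta, _ = planted_delta(["UFFFF", "FFFFU"], 30)
        res = classify_clusters(delta, k=4, patterns=default_pattern_set(), seed=0)
        for gene, cid in res.clusters.assignment.items():
            expected = res.cluster_pattern[cid]
            got = res.gene_pattern[gene]
            assert (got == expected) or (got is None and expected is None) or (
                pd.isna(got) and expected is None)
        sizes = res.clusters.assignment.value_counts()
        n_from_clusters = sum(sizes[cid] for cid, code in res.cluster_pattern.items()
                              if code is not None)
        assert res.n_classified == n_from_clusters

    def test_families_group_clusters_sharing_a_code(self):
        delta, _ = planted_delta(["UFFFF"], 60, noise_sd=0.3)
        res = classify_clusters(delta, k=6, patterns=default_pattern_set(), seed=0)
        for code, cids in res.families.items():
            assert all(res.cluster_pattern[c] == code for c in cids)


class TestClassifyGenesDirectly:
    def test_agrees_with_cluster_mode_on_noiseless_data(self):
        delta, _ = planted_delta(["UFFFF", "FFUFF", "FFFFU"], 20, noise_sd=0.0)
        direct = classify_genes_directly(delta, default_pattern_set())
        clustered = classify_clusters(delta, k=3, patterns=default_pattern_set(), seed=0)
        pd.testing.assert_series_equal(direct.gene_pattern.sort_index(),
                                       clustered.gene_pattern.sort_index())

    def test_simple_trajectories(self):
        em = make_matrix(trajectory_rows({
            "up_ne": [0, 2, 2, 2, 2, 2],
            "subthreshold": [0, 0.5, 0.9, 0.5, 0.5, 0.5],
        }))
        res = classify_genes_directly(subtract_baseline(em), default_pattern_set())
        assert res.gene_pattern["up_ne"] == "UFFFF"
        assert pd.isna(res.gene_pattern["subthreshold"])
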
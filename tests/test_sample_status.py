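import numpy as np
import pandas as pd
import pytest

from fbmeta.quantify import compute_tpm
from fbmeta.sample_status import (
    StatusThresholds,
    bootstrap_support,
    classify_samples,
    distance_matrix,
    pca,
    ward_cluster,
)
from fbmeta.synthetic_data import default_spec, generate, make_transitional


def frame(rows, samples, genes):
    return pd.DataFrame(rows, index=samples, columns=genes, dtype=float)


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        d = distance_matrix(frame([[1, 2], [1, 2]], ["a", "b"], ["g1", "g2"]))
        assert d.loc["a", "b"] == 0

    def test_hand_arithmetic(self):
        d = distance_matrix(frame([[1e6, 0], [0, 1e6]], ["a", "b"], ["g1", "g2"]))
        assert d.loc["a", "b"] == pytest.approx(np.sqrt(2) * 1e6)

    def test_column_permutation_invariant(self):
        data = frame([[1, 2, 3], [4, 5, 6], [7, 1, 2]], ["a", "b", "c"], ["g1", "g2", "g3"])
        d1 = distance_matrix(data)
        d2 = distance_matrix(data[["g3", "g1", "g2"]])
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            distance_matrix(frame([[1.0]], ["a"], ["g1"]))

    def test_symmetric_zero_diagonal_triangle_inequality(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            data = frame(
                rng.uniform(0, 1e6, size=(5, 8)),
                [f"s{i}" for i in range(5)],
                [f"g{j}" for j in range(8)],
            )
            d = distance_matrix(data).to_numpy()
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


class TestPca:
    def test_duplicated_samples_degenerate(self):
        scores, explained = pca(frame([[1, 2], [1, 2], [1, 2]], ["a", "b", "c"], ["g1", "g2"]))
        assert np.allclose(scores.to_numpy(), 0)

    def test_rank_one_explains_everything(self):
        data = frame([[0, 0], [1, 2], [2, 4]], ["a", "b", "c"], ["g1", "g2"])
        _, explained = pca(data)
        assert explained[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_below_one(self):
        rng = np.random.default_rng(2)
        data = frame(rng.normal(size=(6, 10)), [f"s{i}" for i in range(6)], [f"g{j}" for j in range(10)])
        _, explained = pca(data)
        assert 0 < sum(explained) <= 1 + 1e-12

    def test_separates_planted_conditions(self):
        bundle = generate(default_spec(), 5, 5, seed=8)
        tpm = compute_tpm(bundle.mg, bundle.lengths())
        scores, _ = pca(tpm)
        healthy = [s for s, c in bundle.truth.labels.items() if c == "healthy"]
        rotten = [s for s, c in bundle.truth.labels.items() if c == "rotten"]
        h = scores.loc[healthy, "PC1"]
        r = scores.loc[rotten, "PC1"]
        assert h.max() < r.min() or r.max() < h.min()

    def test_deterministic_sign_convention(self):
        data = frame([[1, 5], [2, 1], [9, 2]], ["a", "b", "c"], ["g1", "g2"])
        s1, _ = pca(data)
        s2, _ = pca(data)
        pd.testing.assert_frame_equal(s1, s2)


class TestWardCluster:
    def test_coincident_pair_merges_first(self):
        data = frame([[0, 0], [0, 0], [9, 9]], ["a", "b", "c"], ["g1", "g2"])
        linkage, _ = ward_cluster(distance_matrix(data))
        assert set(linkage[0, :2]) == {0, 1}
        assert linkage[0, 2] == 0

    def test_monotone_merge_heights(self):
        rng = np.random.default_rng(3)
        data = frame(rng.uniform(size=(8, 5)), [f"s{i}" for i in range(8)], [f"g{j}" for j in range(5)])
        linkage, _ = ward_cluster(distance_matrix(data))
        heights = linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_recovers_planted_conditions(self):
        bundle = generate(default_spec(), 5, 5, seed=2)
        tpm = compute_tpm(bundle.mg, bundle.lengths())
        _, clusters = ward_cluster(distance_matrix(tpm), k=2)
        by_condition = pd.Series(bundle.truth.labels)
        assert clusters.groupby(by_condition).nunique().max() == 1
        assert clusters[by_condition == "healthy"].iloc[0] != clusters[by_condition == "rotten"].iloc[0]


class TestBootstrapSupport:
    def test_duplicated_pair_full_support(self):
        data = frame(
            [[1, 2, 3], [1, 2, 3], [9, 9, 9], [5, 1, 7]],
            ["a", "b", "c", "d"],
            ["g1", "g2", "g3"],
        )
        support = bootstrap_support(data, iterations=50, seed=0)
        assert support[frozenset({"a", "b"})] == 1.0

    def test_single_iteration_is_bernoulli(self):
        rng = np.random.default_rng(7)
        data = frame(rng.uniform(size=(5, 6)), [f"s{i}" for i in range(5)], [f"g{j}" for j in range(6)])
        support = bootstrap_support(data, iterations=1, seed=1)
        assert set(support.values()) <= {0.0, 1.0}

    def test_invalid_iterations(self):
        data = frame([[1, 2], [3, 4]], ["a", "b"], ["g1", "g2"])
        with pytest.raises(ValueError):
            bootstrap_support(data, iterations=0, seed=1)

    def test_column_permutation_invariant(self):
        rng = np.random.default_rng(9)
        data = frame(rng.uniform(size=(6, 10)), [f"s{i}" for i in range(6)], [f"g{j:02d}" for j in range(10)])
        shuffled = data[list(rng.permutation(data.columns))]
        s1 = bootstrap_support(data, iterations=25, seed=3)
        s2 = bootstrap_support(shuffled, iterations=25, seed=3)
        assert s1 == s2

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(11)
        data = frame(rng.uniform(size=(5, 8)), [f"s{i}" for i in range(5)], [f"g{j}" for j in range(8)])
        assert bootstrap_support(data, 20, seed=5) == bootstrap_support(data, 20, seed=5)


@pytest.fixture(scope="module")
def bundle():
    return generate(default_spec(), 4, 4, seed=21)


@pytest.fixture(scope="module")
def tpms(bundle):
    lengths = bundle.lengths()
    return compute_tpm(bundle.mg, lengths), compute_tpm(bundle.mt, lengths)


class TestClassifySamples:
    def classify(self, bundle, tpms, putative=None, **kwargs):
        mg, mt = tpms
        return classify_samples(
            mg,
            mt,
            bundle.lineages(),
            "Fomes",
            putative or bundle.truth.labels,
            iterations=kwargs.pop("iterations", 50),
            seed=1,
            **kwargs,
        )

    def test_concordant_samples_retained(self, bundle, tpms):
        report = self.classify(bundle, tpms).report
        assert (report.final_status == pd.Series(bundle.truth.labels)).all()
        assert (report.rationale == "retained").all()

    def test_mislabeled_sample_reassigned_by_cluster(self, bundle, tpms):
        putative = dict(bundle.truth.labels)
        putative["FB01"] = "rotten"  # truly healthy, mg share ~0.8
        report = self.classify(bundle, tpms, putative=putative).report
        assert report.loc["FB01", "final_status"] == "healthy"
        assert report.loc["FB01", "rationale"] == "reassigned_by_cluster"

    def test_transitional_rescued_by_mt(self, bundle, tpms):
        trans = make_transitional(bundle, "FB08", 0.05, 0.60)
        lengths = trans.lengths()
        report = classify_samples(
            compute_tpm(trans.mg, lengths),
            compute_tpm(trans.mt, lengths),
            trans.lineages(),
            "Fomes",
            {**bundle.truth.labels, "FB08": "rotten"},
            iterations=25,
            seed=1,
        ).report
        assert report.loc["FB08", "final_status"] == "healthy"
        assert report.loc["FB08", "rationale"] == "rescued_by_MT"

    def test_transitional_without_mt_signal_is_rotten(self, bundle, tpms):
        trans = make_transitional(bundle, "FB08", 0.05, 0.01)
        lengths = trans.lengths()
        report = classify_samples(
            compute_tpm(trans.mg, lengths),
            compute_tpm(trans.mt, lengths),
            trans.lineages(),
            "Fomes",
            {**bundle.truth.labels, "FB08": "rotten"},
            iterations=25,
            seed=1,
        ).report
        assert report.loc["FB08", "final_status"] == "rotten"

    def test_low_read_sample_excluded_from_mt(self, bundle, tpms):
        trans = make_transitional(bundle, "FB08", 0.05, 0.60)
        lengths = trans.lengths()
        reads = {s: 10_000 for s in bundle.truth.labels}
        reads["FB08"] = 100  # below min_reads: no MT rescue possible
        report = classify_samples(
            compute_tpm(trans.mg, lengths),
            compute_tpm(trans.mt, lengths),
            trans.lineages(),
            "Fomes",
            {**bundle.truth.labels, "FB08": "rotten"},
            mt_read_counts=reads,
            iterations=25,
            seed=1,
        ).report
        assert bool(report.loc["FB08", "mt_excluded"])
        assert report.loc["FB08", "rationale"] == "excluded_low_reads"

    def test_support_and_variance_bounds(self, bundle, tpms):
        result = self.classify(bundle, tpms)
        assert ((result.report.cluster_support >= 0) & (result.report.cluster_support <= 1)).all()
        assert sum(result.explained_variance) <= 1 + 1e-9

    def test_unresolvable_focal_errors(self, bundle, tpms):
        mg, mt = tpms
        with pytest.raises(ValueError, match="focal"):
            classify_samples(mg, mt, bundle.lineages(), "NoSuchTaxon", bundle.truth.labels)
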
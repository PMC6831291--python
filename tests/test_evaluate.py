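import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cfpanel.evaluate import (auroc, cluster_concordance,
                              cross_cohort_validate, pca_embed, roc)
from cfpanel.panel import Panel

from conftest import make_beta


def u_statistic_auroc(scores, labels):
    """Independent oracle: tie-corrected Mann-Whitney U / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ranks = stats.rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    r1 = ranks[labels == 1].sum()
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestRoc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc([1, 2], [1, 1])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        curve = roc(rng.normal(size=30), rng.integers(0, 2, 30) |
                    np.r_[1, np.zeros(29, dtype=int)])
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    def test_matches_u_statistic_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = np.zeros(n, dtype=int)
            labels[:int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            # discrete scores force ties
            scores = rng.integers(0, 6, size=n).astype(float)
            assert auroc(scores, labels) == pytest.approx(
                u_statistic_auroc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=30),
           st.data())
    def test_monotone_transform_invariance(self, scores, data):
        # integer-valued scores keep ties exact under the transforms
        # (arbitrary floats can collapse to spurious ties by rounding)
        n = len(scores)
        labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n,
                                    max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        s = np.array(scores, dtype=float)
        base = auroc(s, labels)
        assert auroc(np.exp(s / 10), labels) == pytest.approx(base, abs=1e-12)
        assert auroc(3 * s + 7, labels) == pytest.approx(base, abs=1e-12)

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=25)
        labels = np.r_[np.zeros(12, dtype=int), np.ones(13, dtype=int)]
        assert auroc(s, labels) + auroc(-s, labels) == pytest.approx(1.0,
                                                                     abs=1e-12)


class TestCrossCohortValidate:
    def _bundle(self, rng, name, shift):
        from cfpanel.data_model import CohortBundle
        from conftest import make_annotation
        probes = ["a", "b"]
        n = 10
        vals = rng.uniform(0.2, 0.5, size=(2 * n, 2))
        vals[n:] += shift
        bm = make_beta(np.clip(vals, 0, 1),
                       ["nontumor"] * n + ["tumor"] * n, probe_ids=probes)
        return CohortBundle(name, bm, make_annotation(probes), "tissue_set_1")

    def test_training_cohort_reproduces_training_auroc(self):
        rng = np.random.default_rng(4)
        bundle = self._bundle(rng, "t1", 0.3)
        panel = Panel(["a", "b"], [1.0, 1.0], "hyper")
        from cfpanel.panel import additive_score
        train = auroc(additive_score(panel, bundle.beta).to_numpy(),
                      bundle.beta.labels01())
        out = cross_cohort_validate(panel, [bundle])
        assert out["t1"].auroc == train

    def test_label_flip_complements_auroc(self):
        rng = np.random.default_rng(5)
        bundle = self._bundle(rng, "t1", 0.3)
        panel = Panel(["a", "b"], [1.0, 1.0], "hyper")
        flipped = self._bundle(rng, "t2", 0.3)
        flipped.beta.group[:] = flipped.beta.group.map(
            {"nontumor": "tumor", "tumor": "nontumor"})
        a = cross_cohort_validate(panel, [bundle])["t1"].auroc
        # same matrix, inverted labels
        bundle.beta.group[:] = bundle.beta.group.map(
            {"nontumor": "tumor", "tumor": "nontumor"})
        b = cross_cohort_validate(panel, [bundle])["t1"].auroc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_missing_probe_names_cohort_and_probe(self):
        rng = np.random.default_rng(6)
        bundle = self._bundle(rng, "t1", 0.3)
        panel = Panel(["a", "zz"], [1.0, 1.0], "hyper")
        with pytest.raises(KeyError, match="t1.*zz"):
            cross_cohort_validate(panel, [bundle])


class TestClusterConcordance:
    def test_separated_blobs_give_diagonal_table(self):
        rng = np.random.default_rng(7)
        n = 10
        vals = np.r_[rng.uniform(0.0, 0.2, size=(n, 5)),
                     rng.uniform(0.8, 1.0, size=(n, 5))]
        bm = make_beta(vals, ["nontumor"] * n + ["tumor"] * n)
        out = cluster_concordance(bm, bm.probe_ids)
        assert out["p_value"] < 1e-4
        table = out["table"].to_numpy()
        # perfect concordance: all mass on one diagonal
        assert max(np.diag(table).sum(),
                   np.diag(np.fliplr(table)).sum()) == 2 * n

    def test_hand_computed_chi_square(self):
        # a perfectly diagonal 2x2 table {{10,0},{0,10}} has chi2 = 20
        obs = np.array([[10, 0], [0, 10]])
        chi2, _, _, _ = stats.chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(20.0)
        rng = np.random.default_rng(8)
        n = 10
        vals = np.r_[rng.uniform(0.0, 0.1, size=(n, 4)),
                     rng.uniform(0.9, 1.0, size=(n, 4))]
        bm = make_beta(vals, ["nontumor"] * n + ["tumor"] * n)
        out = cluster_concordance(bm, bm.probe_ids)
        assert out["chi_square"] == pytest.approx(20.0)

    def test_permuted_labels_are_not_significant_on_average(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(50):
            vals = rng.uniform(0.3, 0.7, size=(16, 6))
            groups = ["nontumor"] * 8 + ["tumor"] * 8
            rng.shuffle(groups)
            bm = make_beta(vals, groups)
            pvals.append(cluster_concordance(bm, bm.probe_ids)["p_value"])
        # under the null, small p-values are rare
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_requires_two_samples_per_group(self):
        bm = make_beta([[0.1], [0.9], [0.5]],
                       ["nontumor", "tumor", "tumor"])
        with pytest.raises(ValueError):
            cluster_concordance(bm, bm.probe_ids)


class TestPca:
    def test_two_samples_single_axis(self):
        bm = make_beta([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9]],
                       ["nontumor", "tumor"])
        res = pca_embed(bm, n_components=2)
        assert res.coordinates["PC1"].nunique() == 2
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(10)
        vals = rng.random((6, 8))
        bm = make_beta(vals, ["nontumor"] * 3 + ["tumor"] * 3)
        res = pca_embed(bm, n_components=6)
        centered = vals - vals.mean(axis=0)
        recon = res.coordinates.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-10)

    def test_groups_separate_along_pc1(self, small_study):
        from sklearn.metrics import silhouette_score
        _, bundles, _ = small_study
        beta = bundles["tissue_set_1"].beta
        res = pca_embed(beta, n_components=2)
        score = silhouette_score(res.coordinates[["PC1"]],
                                 beta.labels01())
        assert score > 0.3
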
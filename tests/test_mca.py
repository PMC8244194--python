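"""MCA signature selection, two-cluster assignment, and silhouette."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methar import mca
from methar.mca import (cluster_and_label_mca, mca_gene_lists,
                        select_mca_cpgs, silhouette_widths, SignatureError)
from methar.synthdata import generate_cohort

import oracles
from conftest import small_config


def _scores(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.standard_normal(n),
                     index=[f"M{i:02d}" for i in range(n)])


class TestSelectMcaCpgs:
    def test_constant_probe_excluded(self):
        score = _scores(10)
        beta = pd.DataFrame(
            [np.full(10, 0.5), 0.5 + 0.3 * score.to_numpy()],
            index=["flat", "tracking"], columns=score.index)
        sig = select_mca_cpgs(beta, score)
        assert "flat" not in sig.probes
        assert "tracking" in sig.probes

    def test_r_exactly_04_included_sd_permitting(self):
        rng = np.random.default_rng(99)
        score = _scores(40, seed=3)
        # construct x with exact Pearson r = 0.4 to the score and high SD
        z = rng.standard_normal(40)
        s = (score - score.mean()) / score.std(ddof=0)
        resid = z - np.dot(z, s) / np.dot(s, s) * s
        resid = (resid - resid.mean()) / resid.std(ddof=0)
        x = 0.4 * s.to_numpy() + np.sqrt(1 - 0.16) * resid
        x = (x - x.mean()) / x.std(ddof=1)
        beta_row = 0.5 + 0.16 * x
        beta = pd.DataFrame([beta_row], index=["cg1"], columns=score.index)
        sd = beta.loc["cg1"].std(ddof=1)
        assert sd > 0.15
        sig = select_mca_cpgs(beta, score, r_min=0.4)
        r = np.corrcoef(beta_row, score)[0, 1]
        assert r == pytest.approx(0.4, abs=1e-9)
        assert "cg1" in sig.probes

    def test_sd_boundary_excludes_at_or_below(self):
        score = pd.Series(np.linspace(-2, 2, 30),
                          index=[f"M{i}" for i in range(30)])
        scaled = (score - score.mean()) / score.std(ddof=1)
        row = 0.5 + 0.15 * scaled / np.sqrt(1 - 1 / 30) * \
            np.sqrt((30 - 1) / 30)
        beta = pd.DataFrame([0.5 + scaled * 0.149 / scaled.std(ddof=1)],
                            index=["low_sd"], columns=score.index)
        assert beta.loc["low_sd"].std(ddof=1) < 0.15
        sig = select_mca_cpgs(beta, score)
        assert "low_sd" not in sig.probes

    def test_planted_recovery_sensitivity_and_fdp(self):
        from methar.preprocess import bmiq_normalize

        cohort = generate_cohort(small_config(seed=77))
        truth = cohort.truth
        m = list(truth.latent_ar_score.index)
        # selection operates on BMIQ-normalized promoter betas, as in the
        # full flow (type-II compression would otherwise deflate the SD)
        normalized = bmiq_normalize(cohort.beta[m], cohort.annotation)
        promoter = cohort.annotation["gene_region_pairs"].map(
            lambda ps: any(r in {"TSS1500", "TSS200", "5UTR"}
                           for _, r in ps))
        beta_m = normalized.loc[promoter.to_numpy()]
        sig = select_mca_cpgs(beta_m, truth.latent_ar_score)
        planted = set(truth.ar_corr_probes.index)
        found = set(sig.probes)
        sensitivity = len(found & planted) / len(planted)
        fdp = len(found - planted - set(truth.ar_block_probes)) / \
            max(len(found), 1)
        assert sensitivity >= 0.8
        assert fdp <= 0.1

    def test_sign_matches_correlation_direction(self):
        cohort = generate_cohort(small_config(seed=78))
        truth = cohort.truth
        m = list(truth.latent_ar_score.index)
        beta_m = cohort.beta.loc[truth.ar_corr_probes.index, m]
        sig = select_mca_cpgs(beta_m, truth.latent_ar_score)
        planted_signs = truth.ar_corr_probes[sig.probes]
        got = sig.entries["sign"].map({"pos": 1, "neg": -1})
        assert (got == planted_signs).mean() > 0.95

    def test_affine_score_rescaling_invariant(self):
        score = _scores(30, seed=5)
        rng = np.random.default_rng(6)
        beta = pd.DataFrame(
            np.clip(0.5 + 0.2 * score.to_numpy()
                    + rng.normal(0, 0.05, size=(50, 30)), 0, 1),
            index=[f"cg{i}" for i in range(50)], columns=score.index)
        a = select_mca_cpgs(beta, score)
        b = select_mca_cpgs(beta, 3.0 * score + 7.0)
        assert a.probes == b.probes
        assert np.allclose(a.entries["pearson_r"], b.entries["pearson_r"])

    def test_too_few_samples_rejected(self):
        score = _scores(2)
        beta = pd.DataFrame(np.random.default_rng(0).uniform(size=(5, 2)),
                            columns=score.index)
        with pytest.raises(SignatureError):
            select_mca_cpgs(beta, score)


class TestClusterAndLabel:
    def _blobs(self, seed, n_probes=60, offset=0.3, noise=0.05, n=30):
        rng = np.random.default_rng(seed)
        labels = np.array(["MCApos"] * (n // 2) + ["MCAneg"] * (n - n // 2))
        rng.shuffle(labels)
        centers = np.where(labels == "MCApos", 0.5 + offset / 2,
                           0.5 - offset / 2)
        beta = pd.DataFrame(
            np.clip(centers[None, :] + rng.normal(0, noise,
                                                  size=(n_probes, n)), 0, 1),
            index=[f"cg{i}" for i in range(n_probes)],
            columns=[f"M{i:02d}" for i in range(n)])
        score = pd.Series(np.where(labels == "MCApos", 1.0, -1.0)
                          + rng.normal(0, 0.3, n), index=beta.columns)
        sig = mca.MCASignature(
            entries=pd.DataFrame({"pearson_r": 0.5, "sd": 0.2,
                                  "sign": "pos"}, index=beta.index),
            r_min=0.4, sd_min=0.15, samples=list(beta.columns))
        return beta, sig, score, pd.Series(labels, index=beta.columns)

    def test_planted_blobs_recovered_with_high_ari(self):
        for seed in range(10):
            beta, sig, score, truth_labels = self._blobs(seed)
            assignment = cluster_and_label_mca(beta, sig, score)
            ari = adjusted_rand_score(truth_labels, assignment.labels)
            assert ari >= 0.9
            # higher-AR cluster labeled positive
            pos = assignment.labels[assignment.labels == "MCA_positive"]
            assert score[pos.index].median() > \
                score[assignment.labels.index.difference(pos.index)].median()

    def test_negating_scores_flips_labels_not_partition(self):
        beta, sig, score, _ = self._blobs(3)
        a = cluster_and_label_mca(beta, sig, score)
        b = cluster_and_label_mca(beta, sig, -score)
        flipped = b.labels.map({"MCA_positive": "MCA_negative",
                                "MCA_negative": "MCA_positive"})
        pd.testing.assert_series_equal(a.labels, flipped)

    def test_empty_signature_rejected(self):
        beta, sig, score, _ = self._blobs(4)
        empty = mca.MCASignature(entries=sig.entries.iloc[:0],
                                 r_min=0.4, sd_min=0.15,
                                 samples=sig.samples)
        with pytest.raises(SignatureError):
            cluster_and_label_mca(beta, empty, score)


class TestSilhouette:
    def test_matches_brute_force_on_random_instance(self, rng):
        x = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        res = silhouette_widths(x, labels)
        expected = oracles.silhouette_oracle(x, labels)
        assert np.allclose(res.widths.to_numpy(), expected, atol=1e-12)
        assert res.average == pytest.approx(expected.mean())

    def test_four_point_hand_instance(self):
        # two tight pairs separated by distance 10 on a line
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        res = silhouette_widths(x, labels)
        # for point 0: a=1, b=(10+11)/2=10.5 -> s=(10.5-1)/10.5
        assert res.widths.iloc[0] == pytest.approx((10.5 - 1) / 10.5)
        assert res.widths.iloc[3] == pytest.approx((10.5 - 1) / 10.5)

    def test_identical_points_width_zero(self):
        x = np.zeros((6, 3))
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = silhouette_widths(x, labels)
        assert np.allclose(res.widths, 0.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(SignatureError):
            silhouette_widths(np.zeros((4, 2)), np.zeros(4))

    def test_separated_clusters_beat_permuted_labels(self, rng):
        beta = np.concatenate([rng.normal(0, 0.5, size=(15, 4)),
                               rng.normal(5, 0.5, size=(15, 4))])
        labels = np.array([0] * 15 + [1] * 15)
        good = silhouette_widths(beta, labels).average
        perm = rng.permutation(labels)
        bad = silhouette_widths(beta, perm).average
        assert good > bad


class TestGeneLists:
    def test_inverse_correlation_threshold(self):
        rng = np.random.default_rng(9)
        samples = [f"M{i:02d}" for i in range(30)]
        base = rng.uniform(0.3, 0.7, size=30)
        beta = pd.DataFrame([base, base], index=["cgA", "cgB"],
                            columns=samples)
        sig = mca.MCASignature(
            entries=pd.DataFrame({"pearson_r": [0.5, 0.5], "sd": 0.2,
                                  "sign": "pos"}, index=["cgA", "cgB"]),
            r_min=0.4, sd_min=0.15, samples=samples)
        ann = pd.DataFrame({"gene_region_pairs":
                            [[("GA", "TSS200")], [("GB", "TSS200")]]},
                           index=["cgA", "cgB"])
        # GA: strong inverse coupling; GB: positive coupling
        expr = pd.DataFrame(
            [8 - 5 * base + rng.normal(0, 0.1, 30),
             2 + 5 * base + rng.normal(0, 0.1, 30)],
            index=["GA_t1", "GB_t1"], columns=samples)
        gene_map = pd.Series({"GA_t1": "GA", "GB_t1": "GB"})
        lists = mca_gene_lists(sig, beta, expr, gene_map, ann)
        assert "GA" in lists["pos"]
        assert "GB" not in lists["pos"] and "GB" not in lists["neg"]

    def test_planted_coupled_genes_recovered(self):
        cohort = generate_cohort(small_config(seed=55))
        truth = cohort.truth
        m = list(truth.latent_ar_score.index)
        beta_m = cohort.beta[
            [s for s in m if s in cohort.expr.columns]]
        sig = select_mca_cpgs(
            cohort.beta.loc[truth.ar_corr_probes.index,
                            [s for s in m if s in cohort.expr.columns]],
            truth.latent_ar_score)
        lists = mca_gene_lists(sig, beta_m, cohort.expr, cohort.gene_map,
                               cohort.annotation)
        expected = {cohort.truth.coupled_genes[p] for p in sig.probes}
        recovered = set(lists["pos"]) | set(lists["neg"])
        assert len(recovered & expected) / len(expected) >= 0.8


class TestDendrogram:
    def test_newick_serialization_contains_all_leaves(self, rng):
        from scipy.cluster.hierarchy import complete
        from scipy.spatial.distance import pdist
        x = rng.normal(size=(6, 3))
        z = complete(pdist(x))
        names = [f"S{i}" for i in range(6)]
        text = mca.dendrogram_newick(z, names)
        assert text.endswith(";")
        for name in names:
            assert name in text
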
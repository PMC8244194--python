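"""BMIQ normalization and the probe/expression filtering rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methar import preprocess
from methar.preprocess import (bmiq_normalize, filter_expression_probes,
                               filter_probes, promoter_variability_subset,
                               quantile_normalize,
                               quantile_normalize_and_center)

import oracles


def _two_type_beta(rng, n_probes=2000, n_samples=3, compression=1.0,
                   type2_fraction=0.5):
    """Betas from a shared 3-state mixture; type-II optionally compressed."""
    states = rng.choice([0.10, 0.50, 0.85], size=n_probes,
                        p=[0.4, 0.2, 0.4])
    a, b = states * 50, (1 - states) * 50
    values = rng.beta(a[:, None], b[:, None], size=(n_probes, n_samples))
    values = np.clip(values, 0.02, 0.98)
    design = np.where(rng.random(n_probes) < type2_fraction, "II", "I")
    type2 = design == "II"
    values[type2] = 0.5 + compression * (values[type2] - 0.5)
    beta = pd.DataFrame(values,
                        index=[f"cg{i:06d}" for i in range(n_probes)],
                        columns=[f"S{j}" for j in range(n_samples)])
    ann = pd.DataFrame({"design_type": design}, index=beta.index)
    return beta, ann


class TestBMIQ:
    def test_identity_limit_when_types_share_distribution(self):
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            beta, ann = _two_type_beta(rng, n_probes=1500, n_samples=1)
            out = bmiq_normalize(beta, ann)
            type2 = ann["design_type"] == "II"
            deltas.append(float((out.loc[type2, "S0"]
                                 - beta.loc[type2, "S0"]).abs().mean()))
        assert np.mean(deltas) < 0.02

    def test_reduces_ks_distance_under_planted_compression(self):
        rng = np.random.default_rng(42)
        beta, ann = _two_type_beta(rng, n_probes=2000, n_samples=2,
                                   compression=0.8)
        out = bmiq_normalize(beta, ann)
        type1 = (ann["design_type"] == "I").to_numpy()
        for col in beta.columns:
            before = stats.ks_2samp(beta.loc[type1, col],
                                    beta.loc[~type1, col]).statistic
            after = stats.ks_2samp(out.loc[type1, col],
                                   out.loc[~type1, col]).statistic
            assert after < before

    def test_type2_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        beta, ann = _two_type_beta(rng, n_probes=800, n_samples=2,
                                   compression=0.8)
        out = bmiq_normalize(beta, ann)
        type2 = ann["design_type"] == "II"
        for col in beta.columns:
            before = np.argsort(beta.loc[type2, col].to_numpy(),
                                kind="mergesort")
            after = np.argsort(out.loc[type2, col].to_numpy(),
                               kind="mergesort")
            assert (before == after).all()

    def test_type1_probes_unchanged(self):
        rng = np.random.default_rng(1)
        beta, ann = _two_type_beta(rng, n_probes=600, compression=0.7)
        out = bmiq_normalize(beta, ann)
        type1 = ann["design_type"] == "I"
        pd.testing.assert_frame_equal(out.loc[type1], beta.loc[type1])

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(2)
        beta, ann = _two_type_beta(rng, n_probes=600, compression=0.6)
        out = bmiq_normalize(beta, ann)
        assert out.to_numpy().min() >= 0.0
        assert out.to_numpy().max() <= 1.0

    def test_missing_probe_type_rejected(self):
        rng = np.random.default_rng(3)
        beta, ann = _two_type_beta(rng, n_probes=200, type2_fraction=0.0)
        with pytest.raises(preprocess.PreconditionError):
            bmiq_normalize(beta, ann)


class TestProbeFilters:
    def _annotated(self, rng, n=1000, n_samples=8):
        beta = pd.DataFrame(
            rng.uniform(0.02, 0.98, size=(n, n_samples)),
            index=[f"cg{i:05d}" for i in range(n)],
            columns=[f"S{j}" for j in range(n_samples)])
        detp = pd.DataFrame(rng.uniform(0, 0.004, size=beta.shape),
                            index=beta.index, columns=beta.columns)
        ann = pd.DataFrame(
            {
                "cross_reactive": rng.random(n) < 0.05,
                "meqtl": rng.random(n) < 0.05,
                "snp_distance_bp": rng.integers(0, 50, size=n).astype(float),
                "design_type": "II",
            },
            index=beta.index)
        return beta, detp, ann

    def test_detection_p_in_single_sample_removes_probe(self, rng):
        beta, detp, ann = self._annotated(rng, n=20, n_samples=94)
        ann[["cross_reactive", "meqtl"]] = False
        ann["snp_distance_bp"] = 100.0
        detp.iloc[4, 57] = 0.06
        filtered, report = filter_probes(beta, detp, ann)
        assert beta.index[4] not in filtered.index
        assert report.removed["detection_p"] == 1
        assert report.retained == 19

    def test_snp_distance_boundary_is_strict(self, rng):
        beta, detp, ann = self._annotated(rng, n=2)
        ann[["cross_reactive", "meqtl"]] = False
        ann["snp_distance_bp"] = [5.0, 4.0]
        filtered, _ = filter_probes(beta, detp, ann)
        assert list(filtered.index) == [beta.index[0]]

    def test_retained_set_matches_brute_force_oracle(self, rng):
        beta, detp, ann = self._annotated(rng, n=1000)
        detp.iloc[rng.integers(0, 1000, 30),
                  rng.integers(0, 8, 30)] = 0.5
        filtered, report = filter_probes(beta, detp, ann)
        expected = oracles.probe_filter_oracle(ann, detp, 0.05, 5.0)
        assert set(filtered.index) == expected
        report.check()

    def test_filter_idempotent(self, rng):
        beta, detp, ann = self._annotated(rng, n=300)
        once, _ = filter_probes(beta, detp, ann)
        twice, report = filter_probes(once, detp.loc[once.index], ann)
        assert list(twice.index) == list(once.index)
        assert sum(report.removed.values()) == 0

    def test_sample_order_does_not_change_retained_set(self, rng):
        beta, detp, ann = self._annotated(rng, n=400)
        cols = list(beta.columns)[::-1]
        a, _ = filter_probes(beta, detp, ann)
        b, _ = filter_probes(beta[cols], detp[cols], ann)
        assert set(a.index) == set(b.index)


class TestPromoterVariabilitySubset:
    def _make(self, betas, regions):
        beta = pd.DataFrame(betas,
                            index=[f"cg{i}" for i in range(len(betas))])
        ann = pd.DataFrame(
            {"gene_region_pairs": [[("G1", r)] if r else [] for r in regions]},
            index=beta.index)
        return beta, ann

    def test_body_only_probe_removed(self):
        beta, ann = self._make([[0.1, 0.9, 0.1, 0.9]] * 2,
                               ["Body", "TSS200"])
        kept, report = promoter_variability_subset(beta, ann)
        assert list(kept.index) == ["cg1"]
        assert report.removed["non_promoter"] == 1

    def test_constant_probe_removed(self):
        beta, ann = self._make([[0.5, 0.5, 0.5, 0.5]], ["TSS1500"])
        kept, _ = promoter_variability_subset(beta, ann)
        assert kept.empty

    def test_alternating_beta_sd_just_above_threshold(self):
        values = [0.2, 0.4] * 47  # 94 samples alternating
        beta, ann = self._make([values], ["5UTR"])
        sd = np.std(values, ddof=1)
        assert sd == pytest.approx(0.1005, abs=0.001)
        kept, report = promoter_variability_subset(beta, ann)
        assert list(kept.index) == ["cg0"]
        assert report.probe_sd.iloc[0] == pytest.approx(sd)

    def test_sd_uses_n_minus_one_denominator(self):
        # sd with ddof=1 is 0.0516 > 0.05; population sd 0.0447 would fail
        values = [0.45, 0.55, 0.45, 0.55, 0.45]
        beta, ann = self._make([values], ["TSS200"])
        kept, _ = promoter_variability_subset(beta, ann)
        assert len(kept) == 1


class TestExpressionPreprocessing:
    def test_transcript_above_threshold_in_one_study_only_dropped(self):
        expr = pd.DataFrame({"A1": [10.0, 300.0], "A2": [20.0, 250.0],
                             "B1": [400.0, 30.0], "B2": [350.0, 20.0]},
                            index=["t1", "t2"])
        kept = filter_expression_probes(
            expr, {"A": 100.0, "B": 100.0},
            {"A": ["A1", "A2"], "B": ["B1", "B2"]})
        assert kept.empty  # each transcript passes in only one study

    def test_all_above_background_everywhere_kept(self, rng):
        expr = pd.DataFrame(rng.uniform(300, 400, size=(20, 4)),
                            columns=["A1", "A2", "B1", "B2"])
        kept = filter_expression_probes(
            expr, {"A": 100.0, "B": 100.0},
            {"A": ["A1", "A2"], "B": ["B1", "B2"]})
        assert len(kept) == 20

    def test_kept_set_matches_enumeration_oracle(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 500, size=(200, 6)),
                            index=[f"t{i}" for i in range(200)],
                            columns=["A1", "A2", "A3", "B1", "B2", "B3"])
        groups = {"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]}
        bg = {"A": 120.0, "B": 80.0}
        kept = filter_expression_probes(expr, bg, groups)
        expected = {
            t for t in expr.index
            if all(any(expr.at[t, s] > 2.0 * bg[g] for s in members)
                   for g, members in groups.items())
        }
        assert set(kept.index) == expected

    def test_empty_study_group_rejected(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 10, size=(5, 2)),
                            columns=["A1", "A2"])
        with pytest.raises(preprocess.PreconditionError):
            filter_expression_probes(expr, {"A": 1.0}, {"A": []})

    def test_identical_columns_unchanged_up_to_centering(self):
        col = np.array([1.0, 5.0, 3.0, 2.0])
        expr = pd.DataFrame({"S1": col, "S2": col, "S3": col})
        qn = quantile_normalize(expr)
        pd.testing.assert_frame_equal(qn, expr, atol=1e-12)
        out = quantile_normalize_and_center(expr, {"A": ["S1", "S2", "S3"]})
        # per-transcript centering of identical columns leaves exact zeros
        assert np.allclose(out.to_numpy(), 0.0)

    def test_columns_share_sorted_values_within_study(self, rng):
        expr = pd.DataFrame(rng.normal(size=(50, 4)),
                            columns=["S1", "S2", "S3", "S4"])
        out = quantile_normalize(expr)
        ref = np.sort(out["S1"].to_numpy())
        for c in out.columns[1:]:
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    def test_toy_matrix_matches_brute_force_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 4)),
                            columns=list("WXYZ"))
        expr.iloc[0, 0] = expr.iloc[1, 0]  # force a tie
        out = quantile_normalize(expr)
        expected = oracles.quantile_normalize_oracle(expr)
        pd.testing.assert_frame_equal(out, expected, atol=1e-12)

    def test_centering_sets_per_transcript_mean_to_zero(self, rng):
        expr = pd.DataFrame(rng.normal(5, 2, size=(30, 6)),
                            columns=[f"S{i}" for i in range(6)])
        out = quantile_normalize_and_center(
            expr, {"A": ["S0", "S1", "S2"], "B": ["S3", "S4", "S5"]})
        assert np.abs(out.mean(axis=1)).max() < 1e-9
        assert out.attrs["centered"]
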
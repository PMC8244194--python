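"""End-to-end orchestration of the analysis on a (synthetic) cohort.

Order of operations: cohort generation -> BMIQ normalization -> probe
filters -> variable promoter subset -> expression normalization -> panel
scores -> delta-beta DM calling and Venn partition -> methylation/
expression integration -> MCA signature, clustering, silhouette -> AR
copy-number calls -> survival analysis (KM, log-rank, Cox with univariate
gating). Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import diffmeth, io_formats, mca, preprocess, survstats
from .scores import AR_ACTIVITY_PANEL, PROLIFERATION_SCORE_PANEL, panel_score
from .synthdata import CohortConfig, SyntheticCohort, generate_cohort

log = logging.getLogger("methar")


def run_all(config: CohortConfig | None = None,
            cohort: SyntheticCohort | None = None,
            outdir: str | Path | None = None) -> dict:
    """Run the whole pipeline; returns a results dict and optionally
    writes every table under `outdir`."""
    if cohort is None:
        cohort = generate_cohort(config or CohortConfig())
    results: dict = {}

    # --- methylation preprocessing ----------------------------------------
    beta_final, filter_reports = preprocess.preprocess_methylation(
        cohort.beta, cohort.detp, cohort.annotation)
    results["filter_reports"] = filter_reports
    results["n_probes_retained"] = beta_final.shape[0]

    # --- expression normalization ------------------------------------------
    expr_norm = preprocess.quantile_normalize_and_center(
        cohort.expr, {"study": list(cohort.expr.columns)})

    samples = cohort.samples
    n_ids = list(samples.index[samples["tissue"] == "N"])
    t_ids = list(samples.index[samples["tissue"] == "T"])
    m_ids = list(samples.index[samples["tissue"] == "M"])
    m_scored = [s for s in m_ids if s in expr_norm.columns]

    # --- panel scores -------------------------------------------------------
    ar_vec = panel_score(expr_norm, AR_ACTIVITY_PANEL, cohort.gene_map,
                         samples=m_scored)
    prolif_vec = panel_score(expr_norm, PROLIFERATION_SCORE_PANEL,
                             cohort.gene_map, samples=m_scored)
    results["ar_scores"] = ar_vec.scores
    results["prolif_scores"] = prolif_vec.scores

    # --- differential methylation ------------------------------------------
    ann = cohort.annotation
    dm_tn = diffmeth.call_dm_cpgs(beta_final, samples, "T", "N",
                                  annotation=ann)
    dm_mn = diffmeth.call_dm_cpgs(beta_final, samples, "M", "N",
                                  annotation=ann)
    dm_mt = diffmeth.call_dm_cpgs(beta_final, samples, "M", "T",
                                  annotation=ann)
    partition = diffmeth.partition_dm_sets(dm_tn, dm_mn, dm_mt)
    results["dm"] = {"TN": dm_tn, "MN": dm_mn, "MT": dm_mt}
    results["partition"] = partition

    unique_mt_records = [r for r in dm_mt
                         if r.probe_id in partition.unique_mt]
    integration_tn = diffmeth.integrate_methylation_expression(
        dm_tn, beta_final, expr_norm, cohort.gene_map, t_ids, n_ids)
    integration_mt = diffmeth.integrate_methylation_expression(
        unique_mt_records, beta_final, expr_norm, cohort.gene_map,
        m_scored, t_ids)
    results["integration_tn"] = integration_tn
    results["integration_mt"] = integration_mt

    # --- MCA ----------------------------------------------------------------
    beta_m = beta_final[m_scored]
    signature = mca.select_mca_cpgs(beta_m, ar_vec.scores)
    results["signature"] = signature
    assignment = None
    silhouette = None
    gene_lists = None
    if len(signature) >= 1:
        assignment = mca.cluster_and_label_mca(beta_m, signature,
                                               ar_vec.scores)
        silhouette = mca.silhouette_widths(
            beta_m.loc[signature.probes].T, assignment.labels)
        gene_lists = mca.mca_gene_lists(signature, beta_m, expr_norm,
                                        cohort.gene_map, ann)
    results["assignment"] = assignment
    results["silhouette"] = silhouette
    results["gene_lists"] = gene_lists

    # --- AR copy number -----------------------------------------------------
    ar_probes = cnv_mod.region_probes_from_annotation(ann, "AR")
    cnv_calls = cnv_mod.call_cohort_cnv(cohort.intensity, n_ids, m_ids,
                                        ar_probes, region="AR")
    results["cnv"] = cnv_calls

    # --- survival -----------------------------------------------------------
    surv = cohort.survival.copy()
    patient_to_sample = {f"MP{j + 1:02d}": f"M{j + 1:02d}"
                         for j in range(len(m_ids))}
    surv["sample_id"] = [patient_to_sample.get(p) for p in surv.index]
    surv = surv[surv["sample_id"].notna()].copy()
    if assignment is not None:
        surv["mca_label"] = surv["sample_id"].map(assignment.labels)
        surv["ar_score"] = surv["sample_id"].map(ar_vec.scores)
        surv["prolif_score"] = surv["sample_id"].map(prolif_vec.scores)
        surv["ar_amplified"] = surv["sample_id"].map(
            cnv_calls["status"] == "amplified").astype(float)
        surv["met_subtype"] = surv["sample_id"].map(samples["met_subtype"])
        surv["age"] = surv["sample_id"].map(samples["age"])
        surv["serum_psa"] = surv["sample_id"].map(samples["serum_psa"])
        analyzed = surv[surv["mca_label"].notna()
                        & (surv["met_subtype"] != "NA")].copy()
        analyzed["mca_negative"] = (analyzed["mca_label"]
                                    == "MCA_negative").astype(float)
        km = survstats.km_curve(analyzed, "mca_label")
        lr_stat, lr_p = survstats.logrank_test(analyzed, "mca_label")
        uni, multi = survstats.cox_fit(
            analyzed,
            ["mca_negative", "ar_score", "prolif_score", "ar_amplified",
             "age", "met_subtype", "serum_psa"],
            factor_reference={"met_subtype": "MetA"})
        results["survival"] = {
            "table": analyzed, "km": km,
            "logrank": {"statistic": lr_stat, "p": lr_p},
            "cox_univariate": uni, "cox_multivariate": multi,
        }

    results["summary"] = _summarize(results)
    if outdir is not None:
        _write_outputs(results, cohort, beta_final, Path(outdir))
    return results


def _summarize(results: dict) -> dict:
    partition: diffmeth.DMPartition = results["partition"]
    dm = results["dm"]
    summary = {
        "n_probes_retained": int(results["n_probes_retained"]),
        "dm_counts": {k: len(v) for k, v in dm.items()},
        "dm_hyper_hypo": partition.hyper_hypo,
        "unique_mt_count": len(partition.unique_mt),
        "venn_region_sizes": partition.region_sizes,
        "signature_n_cpgs": len(results["signature"]),
    }
    for name, recs in (("integration_tn", results["integration_tn"]),
                       ("integration_mt", results["integration_mt"])):
        classes = diffmeth.classify_genes(recs)
        counts: dict[str, int] = {}
        for c in classes.values():
            counts[c] = counts.get(c, 0) + 1
        summary[f"{name}_gene_classes"] = counts
    if results["assignment"] is not None:
        labels = results["assignment"].labels
        summary["mca_cluster_sizes"] = labels.value_counts().to_dict()
        summary["mca_median_ar"] = results["assignment"].median_ar
        summary["silhouette_average"] = results["silhouette"].average
    cnv_calls = results["cnv"]
    summary["ar_amplified_fraction"] = float(
        (cnv_calls["status"] == "amplified").mean())
    if "survival" in results:
        surv = results["survival"]
        summary["km_median_months"] = {
            g: c.median for g, c in surv["km"].items()}
        summary["logrank_p"] = surv["logrank"]["p"]
        summary["cox"] = {
            f"{r.model}:{r.covariate}": {"RR": r.hazard_ratio, "P": r.p}
            for r in surv["cox_univariate"] + surv["cox_multivariate"]}
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str)
                if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _write_outputs(results: dict, cohort: SyntheticCohort,
                   beta_final: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_matrix(beta_final, outdir / "beta_filtered.tsv", "beta")
    (outdir / "filter_reports.json").write_text(
        json.dumps(_jsonable(results["filter_reports"]), indent=1))
    for name, recs in results["dm"].items():
        diffmeth.dm_records_frame(recs).to_csv(
            outdir / f"dm_{name}.tsv", sep="\t", index=False,
            float_format="%.6f")
    (outdir / "partition.json").write_text(json.dumps(
        _jsonable({"region_sizes": results["partition"].region_sizes,
                   "unique_mt": sorted(results["partition"].unique_mt)}),
        indent=1))
    diffmeth.integration_frame(results["integration_tn"]).to_csv(
        outdir / "integration_TN.tsv", sep="\t", index=False,
        float_format="%.6g")
    diffmeth.integration_frame(results["integration_mt"]).to_csv(
        outdir / "integration_MT.tsv", sep="\t", index=False,
        float_format="%.6g")
    pd.DataFrame({"ar_score": results["ar_scores"],
                  "prolif_score": results["prolif_scores"]}) \
        .rename_axis("sample_id") \
        .to_csv(outdir / "scores.tsv", sep="\t", float_format="%.8f")
    signature = results["signature"]
    signature.entries.rename_axis("probe_id").to_csv(
        outdir / "mca_signature.tsv", sep="\t", float_format="%.6f")
    if results["assignment"] is not None:
        results["assignment"].labels.rename("mca_label") \
            .rename_axis("sample_id").reset_index() \
            .to_csv(outdir / "mca_assignment.csv", index=False)
        (outdir / "silhouette.json").write_text(json.dumps(_jsonable(
            {"average": results["silhouette"].average,
             "widths": results["silhouette"].widths.round(8).to_dict()}),
            indent=1))
        (outdir / "mca_gene_lists.json").write_text(
            json.dumps(_jsonable(results["gene_lists"]), indent=1))
        z = results["assignment"].linkage_matrix
        newick = mca.dendrogram_newick(
            z, [s for s in beta_final.columns
                if s in results["assignment"].labels.index])
        (outdir / "mca_dendrogram.nwk").write_text(newick)
    results["cnv"].to_csv(outdir / "cnv_AR.csv", float_format="%.6f")
    if "survival" in results:
        surv = results["survival"]
        rows = []
        for g, curve in surv["km"].items():
            for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                rows.append({"group": g, "months": t, "survival": s,
                             "at_risk": r})
        pd.DataFrame(rows).to_csv(outdir / "km_steps.tsv", sep="\t",
                                  index=False, float_format="%.6f")
        survstats.cox_results_frame(
            surv["cox_univariate"] + surv["cox_multivariate"]).to_csv(
            outdir / "cox.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(results["summary"]), indent=1, sort_keys=True))
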
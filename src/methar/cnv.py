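"""Reference-ratio copy-number assessment from array intensities.

Total methylation-array intensity (methylated + unmethylated signal) is
roughly proportional to local copy number. Each query sample is compared
probe-wise against the mean of a set of reference (non-malignant) samples
on the log2 scale, median-centered to absorb global scaling, and a region
of interest (the AR gene by default) is summarized by a 10%-trimmed mean.
Calls use symmetric thresholds (default +/-0.3) in place of the manual
inspection a human analyst would perform on the segmented profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .io_formats import MetharError

log = logging.getLogger("methar")


class CNVError(MetharError):
    pass


@dataclass
class CNVResult:
    sample_id: str
    region: str
    region_statistic: float        # 10%-trimmed mean of centered log2 ratios
    status: str                    # amplified / normal / loss
    amp_threshold: float
    loss_threshold: float
    n_region_probes: int


def cnv_log2_ratios(intensity: pd.DataFrame, reference_samples: list[str],
                    query_sample: str, pseudocount: float = 1.0
                    ) -> pd.Series:
    """Median-centered per-probe log2 ratios of query vs reference mean.

    ratio_p = log2((I_query,p + pc) / (mean_ref(I_ref,p) + pc)), then the
    query's median ratio over all probes is subtracted, which removes any
    global intensity scaling of the sample. Probes whose reference mean is
    zero are skipped with a log entry.
    """
    if len(reference_samples) < 2:
        raise CNVError("need >= 2 reference samples")
    missing = set(reference_samples + [query_sample]) - set(intensity.columns)
    if missing:
        raise CNVError(f"samples absent from intensity matrix: "
                       f"{sorted(missing)}")
    ref_mean = intensity[reference_samples].mean(axis=1)
    usable = ref_mean > 0
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("cnv_log2_ratios: skipped %d all-zero reference probes",
                 n_skipped)
    query = intensity.loc[usable, query_sample]
    ratios = np.log2((query + pseudocount)
                     / (ref_mean[usable] + pseudocount))
    return ratios - ratios.median()


def call_region_cnv(ratios: pd.Series, region_probes: list[str],
                    region: str = "AR", amp_threshold: float = 0.3,
                    loss_threshold: float = -0.3,
                    sample_id: str = "") -> CNVResult:
    """Call a region amplified/normal/loss from its trimmed-mean ratio.

    The region statistic is the 10%-trimmed mean (10% cut from each tail)
    of the region's centered log2 ratios; amplified iff it reaches
    `amp_threshold`, loss iff it reaches `loss_threshold`.
    """
    present = [p for p in region_probes if p in ratios.index]
    if len(present) < 3:
        raise CNVError(f"region {region!r} has {len(present)} probes with "
                       "ratios; need >= 3")
    stat = float(trim_mean(ratios[present].to_numpy(dtype=float), 0.1))
    if stat >= amp_threshold:
        status = "amplified"
    elif stat <= loss_threshold:
        status = "loss"
    else:
        status = "normal"
    return CNVResult(sample_id=sample_id, region=region,
                     region_statistic=stat, status=status,
                     amp_threshold=amp_threshold,
                     loss_threshold=loss_threshold,
                     n_region_probes=len(present))


def region_probes_from_annotation(annotation: pd.DataFrame,
                                  gene: str = "AR") -> list[str]:
    """Probes mapped to `gene` in the manifest (any region class)."""
    hits = annotation["gene_region_pairs"].map(
        lambda ps: any(g == gene for g, _ in ps))
    return list(annotation.index[hits])


def call_cohort_cnv(intensity: pd.DataFrame, reference_samples: list[str],
                    query_samples: list[str], region_probes: list[str],
                    region: str = "AR", amp_threshold: float = 0.3,
                    loss_threshold: float = -0.3,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-sample CNV calls for a region over a list of query samples."""
    rows = []
    for sample in query_samples:
        ratios = cnv_log2_ratios(intensity, reference_samples, sample,
                                 pseudocount=pseudocount)
        res = call_region_cnv(ratios, region_probes, region=region,
                              amp_threshold=amp_threshold,
                              loss_threshold=loss_threshold,
                              sample_id=sample)
        rows.append({"sample_id": sample, "region": region,
                     "log2_ratio": res.region_statistic,
                     "status": res.status})
    return pd.DataFrame(rows).set_index("sample_id")
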
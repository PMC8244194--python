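"""Readers and writers for every table the pipeline touches.

Conventions: TSV for numeric matrices (first column = row id, header =
sample ids, beta values at 6-decimal fixed precision), CSV for metadata.
Coordinates are 1-based inclusive (Illumina MAPINFO convention); the genome
build label (hg19) is carried as metadata only. All readers validate; they
never silently drop rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("methar")

MATRIX_KINDS = ("beta", "detp", "intensity", "expression")

TISSUES = {"N", "T", "M"}
TREATMENTS = {"HN", "ST", "CRPC", "NA"}
MET_SUBTYPES = {"MetA", "MetB", "MetC", "NA"}
REGIONS = {"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"}
PROMOTER_REGIONS = {"TSS1500", "TSS200", "5UTR"}
DESIGN_TYPES = {"I", "II"}

MANIFEST_COLUMNS = [
    "IlmnID", "CHR", "MAPINFO", "Strand", "Infinium_Design_Type",
    "UCSC_RefGene_Name", "UCSC_RefGene_Group",
    "Flag_CrossReactive", "Flag_meQTL", "SNP_distance_bp",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "patient_id", "tissue", "treatment", "epithelial_fraction",
    "met_subtype", "ar_amplified", "serum_psa", "age",
]


class MetharError(Exception):
    """Base class for all package errors."""


class FormatError(MetharError):
    """Malformed file: duplicates, ragged rows, missing columns."""


class ValidationError(MetharError):
    """Well-formed file with out-of-range or inconsistent values."""


class VocabularyError(ValidationError):
    """A categorical field holds a token outside its closed vocabulary."""


# ---------------------------------------------------------------------------
# numeric matrices


def _check_axes(df: pd.DataFrame, what: str) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{what}: duplicate row id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{what}: duplicate sample id {dup!r}")


def validate_matrix(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Validate a probes/transcripts x samples matrix in place.

    beta and detp must lie in [0, 1]; intensity must be non-negative;
    expression is unconstrained. NaN cells are rejected for all kinds.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    _check_axes(df, kind)
    values = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"{kind}: non-finite value at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}")
    if kind in ("beta", "detp"):
        bad = np.argwhere((values < 0.0) | (values > 1.0))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"{kind}: value {values[bad[0][0], bad[0][1]]!r} outside "
                f"[0, 1] at probe {df.index[r]!r}, sample {df.columns[c]!r}")
    elif kind == "intensity":
        bad = np.argwhere(values < 0.0)
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"intensity: negative value at probe {df.index[r]!r}, "
                f"sample {df.columns[c]!r}")
    return df


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a TSV matrix (rows x samples) and validate it for `kind`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    return validate_matrix(df, kind)


def write_matrix(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a validated matrix as TSV; beta/detp at 6-decimal precision."""
    validate_matrix(df, kind)
    fmt = "%.6f" if kind in ("beta", "detp") else "%.6g"
    df.to_csv(path, sep="\t", float_format=fmt)


# ---------------------------------------------------------------------------
# probe annotation (Illumina-manifest-like CSV)


def _zip_gene_regions(genes: str, groups: str, probe: str) -> list[tuple[str, str]]:
    genes = "" if pd.isna(genes) else str(genes).strip()
    groups = "" if pd.isna(groups) else str(groups).strip()
    if not genes and not groups:
        return []
    glist = genes.split(";") if genes else []
    rlist = groups.split(";") if groups else []
    if len(glist) != len(rlist):
        raise FormatError(
            f"probe {probe!r}: gene list length {len(glist)} != region list "
            f"length {len(rlist)}")
    for region in rlist:
        if region not in REGIONS:
            raise VocabularyError(
                f"probe {probe!r}: unknown region token {region!r}")
    return list(zip(glist, rlist))


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV into a probe annotation frame.

    Returns a frame indexed by probe_id with columns chrom, pos, strand,
    design_type, gene_region_pairs (list of (gene, region) tuples), and the
    boolean flags cross_reactive, meqtl, near_snp (SNP closer than 5 bp).
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest columns {missing}")
    if raw["IlmnID"].duplicated().any():
        dup = raw["IlmnID"][raw["IlmnID"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    bad = set(raw["Infinium_Design_Type"]) - DESIGN_TYPES
    if bad:
        raise VocabularyError(f"{path}: unknown design type {bad}")
    pos = raw["MAPINFO"].astype(int)
    if (pos < 1).any():
        raise ValidationError(f"{path}: MAPINFO must be >= 1 (1-based)")
    snp_bp = raw["SNP_distance_bp"].astype(float)
    pairs = [
        _zip_gene_regions(g, r, p)
        for p, g, r in zip(raw["IlmnID"], raw["UCSC_RefGene_Name"],
                           raw["UCSC_RefGene_Group"])
    ]
    ann = pd.DataFrame(
        {
            "chrom": raw["CHR"].to_numpy(),
            "pos": pos.to_numpy(),
            "strand": raw["Strand"].to_numpy(),
            "design_type": raw["Infinium_Design_Type"].to_numpy(),
            "gene_region_pairs": pairs,
            "cross_reactive": raw["Flag_CrossReactive"].astype(int).astype(bool).to_numpy(),
            "meqtl": raw["Flag_meQTL"].astype(int).astype(bool).to_numpy(),
            "snp_distance_bp": snp_bp.to_numpy(),
        },
        index=pd.Index(raw["IlmnID"], name="probe_id"),
    )
    ann["near_snp"] = ann["snp_distance_bp"] < 5
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "IlmnID": ann.index,
            "CHR": ann["chrom"].to_numpy(),
            "MAPINFO": ann["pos"].to_numpy(),
            "Strand": ann["strand"].to_numpy(),
            "Infinium_Design_Type": ann["design_type"].to_numpy(),
            "UCSC_RefGene_Name": [
                ";".join(g for g, _ in pairs) for pairs in ann["gene_region_pairs"]
            ],
            "UCSC_RefGene_Group": [
                ";".join(r for _, r in pairs) for pairs in ann["gene_region_pairs"]
            ],
            "Flag_CrossReactive": ann["cross_reactive"].astype(int).to_numpy(),
            "Flag_meQTL": ann["meqtl"].astype(int).to_numpy(),
            "SNP_distance_bp": ann["snp_distance_bp"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


def promoter_genes(pairs: list[tuple[str, str]]) -> list[str]:
    """Genes mapped to a promoter class (TSS1500/TSS200/5UTR) in a pair list."""
    seen: list[str] = []
    for gene, region in pairs:
        if region in PROMOTER_REGIONS and gene not in seen:
            seen.append(gene)
    return seen


# ---------------------------------------------------------------------------
# sample sheet / survival


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and vocabulary-validate the sample sheet CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sample sheet columns {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    return validate_sample_sheet(df.set_index("sample_id"))


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["tissue"]) - TISSUES
    if bad:
        raise VocabularyError(f"unknown tissue token(s) {sorted(bad)}")
    bad = set(df["treatment"]) - TREATMENTS
    if bad:
        raise VocabularyError(f"unknown treatment token(s) {sorted(bad)}")
    bad = set(df["met_subtype"]) - MET_SUBTYPES
    if bad:
        raise VocabularyError(f"unknown met_subtype token(s) {sorted(bad)}")
    for col in ("epithelial_fraction", "serum_psa", "age"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == "NA"))
    ef = df["epithelial_fraction"]
    if ((ef < 0) | (ef > 100)).any():
        raise ValidationError("epithelial_fraction outside [0, 100]")
    # paired N/T samples must share a patient
    for patient, grp in df[df["tissue"].isin(["N", "T"])].groupby("patient_id"):
        if set(grp["tissue"]) not in ({"N"}, {"T"}, {"N", "T"}):
            raise ValidationError(f"patient {patient!r}: bad N/T pairing")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index()
    out.to_csv(path, index=False, na_rep="NA")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read the survival CSV (patient_id, months, event [, covariates])."""
    df = pd.read_csv(path)
    for col in ("patient_id", "months", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing survival column {col!r}")
    df = df.set_index("patient_id")
    if (df["months"] <= 0).any():
        raise ValidationError("survival months must be > 0")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValidationError("event flag must be 0 or 1")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, index=False, na_rep="NA")
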
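"""Schema and invariant checks for the pipeline's tabular inputs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Issue", "validate_roi", "validate_series", "validate_coverage",
           "validate_contigs", "validate_profile", "validate_tables"]


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    table: str
    row: int | None
    message: str


def _require_columns(df: pd.DataFrame, table: str, columns) -> list[Issue]:
    missing = [c for c in columns if c not in df.columns]
    return [Issue("error", table, None, f"missing column {c!r}") for c in missing]


def _rows_where(mask) -> list[int]:
    return list(np.flatnonzero(np.asarray(mask)))


def validate_roi(df: pd.DataFrame) -> list[Issue]:
    issues = _require_columns(
        df, "roi", ["roi_id", "site", "depth_m", "substrate", "timepoint_h", "ratio_15N"]
    )
    if issues:
        return issues
    for i in _rows_where(df["ratio_15N"] < 0):
        issues.append(Issue("error", "roi", i, "negative ratio_15N"))
    if "ratio_13C" in df.columns:
        bad = df["ratio_13C"].notna() & (df["ratio_13C"] < 0)
        for i in _rows_where(bad):
            issues.append(Issue("error", "roi", i, "negative ratio_13C"))
    for i in _rows_where(df["timepoint_h"] < 0):
        issues.append(Issue("error", "roi", i, "negative timepoint"))
    for (site, substrate), grp in df.groupby(["site", "substrate"]):
        if (grp["timepoint_h"] == 0).sum() < 2:
            issues.append(
                Issue("error", "roi", None,
                      f"{site}/{substrate}: fewer than 2 cells at 0 h (no baseline)")
            )
    return issues


def validate_series(df: pd.DataFrame) -> list[Issue]:
    issues = _require_columns(
        df, "nitrif",
        ["site", "depth_m", "substrate", "replicate_id", "timepoint_h",
         "delta15N_NOx_permil", "nox_uM"],
    )
    if issues:
        return issues
    for i in _rows_where(df["nox_uM"] <= 0):
        issues.append(Issue("error", "nitrif", i, "non-positive NOx concentration"))
    for i in _rows_where(df["delta15N_NOx_permil"] <= -1000):
        issues.append(Issue("error", "nitrif", i, "delta15N <= -1000 permil"))
    for key, grp in df.groupby(["site", "depth_m", "substrate"]):
        if grp["timepoint_h"].nunique() < 2:
            issues.append(
                Issue("warning", "nitrif", None, f"{key}: fewer than 2 distinct timepoints")
            )
    return issues


def validate_coverage(df: pd.DataFrame) -> list[Issue]:
    issues = _require_columns(
        df, "gene_coverage",
        ["sample_id", "gene", "contig_id", "mapped_reads", "gene_length_bp",
         "library_mapped_reads"],
    )
    if issues:
        return issues
    for i in _rows_where(df["mapped_reads"] < 0):
        issues.append(Issue("error", "gene_coverage", i, "negative read count"))
    for i in _rows_where(df["gene_length_bp"] <= 0):
        issues.append(Issue("error", "gene_coverage", i, "non-positive gene length"))
    for i in _rows_where(df["library_mapped_reads"] <= 0):
        issues.append(Issue("error", "gene_coverage", i, "non-positive library size"))
    if "breadth" in df.columns:
        for i in _rows_where((df["breadth"] < 0) | (df["breadth"] > 1)):
            issues.append(Issue("error", "gene_coverage", i, "breadth outside [0, 1]"))
    for sample, grp in df.groupby("sample_id"):
        if not (grp["gene"] == "recA").any():
            issues.append(
                Issue("warning", "gene_coverage", None,
                      f"sample {sample!r}: no recA record (ratios will be undefined)")
            )
    return issues


def validate_contigs(df: pd.DataFrame) -> list[Issue]:
    issues = _require_columns(
        df, "contig_hits",
        ["contig_id", "sample_id", "length_bp", "gene_taxa", "coverage", "breadth"],
    )
    if issues:
        return issues
    for i in _rows_where((df["breadth"] < 0) | (df["breadth"] > 1)):
        issues.append(Issue("error", "contig_hits", i, "breadth outside [0, 1]"))
    for i in _rows_where(df["coverage"] < 0):
        issues.append(Issue("error", "contig_hits", i, "negative coverage"))
    for i in _rows_where(df["length_bp"] <= 0):
        issues.append(Issue("error", "contig_hits", i, "non-positive contig length"))
    return issues


def validate_profile(df: pd.DataFrame) -> list[Issue]:
    issues = _require_columns(df, "profile", ["depth_m", "cells_per_L"])
    if issues:
        return issues
    for i in _rows_where(df["cells_per_L"] < 0):
        issues.append(Issue("error", "profile", i, "negative cell density"))
    if df["depth_m"].duplicated().any():
        issues.append(Issue("error", "profile", None, "duplicate depths"))
    return issues


_VALIDATORS = {
    "roi": validate_roi,
    "nitrif": validate_series,
    "gene_coverage": validate_coverage,
    "contig_hits": validate_contigs,
    "profile": validate_profile,
}


def validate_tables(tables: dict[str, pd.DataFrame]) -> list[Issue]:
    """Validate every provided table; unknown names raise KeyError."""
    issues: list[Issue] = []
    for name, df in tables.items():
        issues.extend(_VALIDATORS[name](df))
    return issues
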
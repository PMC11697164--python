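"""Marker-gene abundance, copy-number-corrected prevalence and contig taxonomy.

Works on tabular mapping summaries (per-gene mapped reads, gene length,
library size, breadth) produced upstream by a read mapper. Gene abundances
are expressed as RPKM (reads per kilobase of gene per million mapped reads)
and normalized to the single-copy housekeeping gene recA to estimate the
fraction of cells ("genome equivalents") carrying a gene of interest. For
ureC the ratio is further divided by the mean ureC copy number per genome
observed in assembled genomes (default 1.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_URE_C_COPY_NUMBER",
    "rpkm",
    "marker_ratio",
    "prevalence_from_ratio",
    "prevalence_table",
    "parse_taxonomy",
    "contig_consensus_taxonomy",
    "ureC_taxon_relabund",
    "DepthTrendResult",
    "depth_trend_test",
]

#: Mean ureC copies per genome in the reference MAG set.
DEFAULT_URE_C_COPY_NUMBER = 1.1


def rpkm(mapped_reads, gene_length_bp, library_mapped_reads):
    """Reads per kilobase of gene per million mapped library reads."""
    reads = np.asarray(mapped_reads, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_mapped_reads, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    out = reads / (length / 1000.0) / (lib / 1e6)
    return out if out.ndim else float(out)


def marker_ratio(rpkm_gene: float, rpkm_recA: float) -> float:
    """Gene abundance relative to recA (genome equivalents)."""
    if rpkm_recA <= 0:
        raise ValueError("recA RPKM must be positive; ratio undefined")
    return rpkm_gene / rpkm_recA


def prevalence_from_ratio(
    ratio: float, copy_number: float = DEFAULT_URE_C_COPY_NUMBER
) -> float:
    """Estimated fraction of cells carrying the gene.

    Divides the gene/recA ratio by the mean gene copies per carrier genome.
    Values above 1 are returned unclipped (they flag copy-number or mapping
    artifacts; see :func:`prevalence_table`).
    """
    if copy_number <= 0:
        raise ValueError("copy number must be positive")
    return ratio / copy_number


def prevalence_table(
    coverage: pd.DataFrame,
    copy_number: float = DEFAULT_URE_C_COPY_NUMBER,
) -> pd.DataFrame:
    """Per-sample RPKMs, marker ratios and ureC prevalence.

    ``coverage`` columns: sample_id, gene, contig_id, mapped_reads,
    gene_length_bp, library_mapped_reads. Gene RPKMs are summed across
    contigs within a sample before ratios are formed. A sample without recA
    raises (the ratio is undefined).
    """
    rows = []
    for sample, grp in coverage.groupby("sample_id", sort=True):
        per_gene = {}
        for gene, g in grp.groupby("gene"):
            per_gene[gene] = float(
                np.sum(rpkm(g["mapped_reads"], g["gene_length_bp"], g["library_mapped_reads"]))
            )
        if per_gene.get("recA", 0.0) <= 0:
            raise ValueError(f"sample {sample!r}: recA coverage absent; ratios undefined")
        r_urec = marker_ratio(per_gene.get("ureC", 0.0), per_gene["recA"])
        r_amoa = marker_ratio(per_gene.get("amoA", 0.0), per_gene["recA"])
        prev = prevalence_from_ratio(r_urec, copy_number)
        if prev > 1:
            warnings.warn(
                f"sample {sample!r}: ureC prevalence {prev:.3f} > 1 "
                "(copy-number or mapping artifact)",
                stacklevel=2,
            )
        rows.append(
            {
                "sample_id": sample,
                "rpkm_ureC": per_gene.get("ureC", 0.0),
                "rpkm_recA": per_gene["recA"],
                "rpkm_amoA": per_gene.get("amoA", 0.0),
                "ratio_ureC_recA": r_urec,
                "ratio_amoA_recA": r_amoa,
                "prevalence_ureC": prev,
                "prevalence_flagged": prev > 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contig consensus taxonomy
# ---------------------------------------------------------------------------

def parse_taxonomy(path) -> tuple[str, ...]:
    """Split a semicolon-delimited taxonomy string into a rank tuple."""
    if isinstance(path, str):
        return tuple(p.strip() for p in path.split(";") if p.strip())
    return tuple(path)


def contig_consensus_taxonomy(
    gene_taxa: Iterable, majority_threshold: float = 0.5
) -> tuple[str, ...]:
    """Majority-vote consensus taxonomy over a contig's gene-level calls.

    Walks ranks root to leaf; at each rank the taxon carried by strictly more
    than ``majority_threshold`` of the contig's classified genes (and
    consistent with the retained path so far) is kept. The walk stops at the
    first rank without a qualifying majority. Zero classified genes yield an
    empty path (unclassified).
    """
    paths = [parse_taxonomy(p) for p in gene_taxa]
    paths = [p for p in paths if p]
    n = len(paths)
    if n == 0:
        return ()
    consensus: list[str] = []
    rank = 0
    while True:
        votes: dict[str, int] = {}
        for p in paths:
            if len(p) > rank and tuple(p[:rank]) == tuple(consensus):
                votes[p[rank]] = votes.get(p[rank], 0) + 1
        winner = None
        for taxon, count in votes.items():
            if count > majority_threshold * n:
                winner = taxon
                break
        if winner is None:
            break
        consensus.append(winner)
        rank += 1
    return tuple(consensus)


def ureC_taxon_relabund(
    contigs: pd.DataFrame,
    min_breadth: float = 0.5,
    min_length_bp: int = 3000,
    majority_threshold: float = 0.5,
) -> pd.Series:
    """Coverage-weighted taxonomic composition of ureC-encoding contigs.

    ``contigs`` columns: contig_id, length_bp, coverage, breadth, gene_taxa
    (comma-separated list of semicolon-delimited paths). Contigs failing the
    breadth or length filter are excluded from both numerator and
    denominator. Each passing contig is labeled by the terminal taxon of its
    consensus path ("unclassified" when empty). Returns fractions summing
    to 1; empty with a warning when nothing passes.
    """
    passing = contigs[
        (contigs["breadth"] >= min_breadth) & (contigs["length_bp"] >= min_length_bp)
    ]
    if passing.empty:
        warnings.warn("no contig passes the breadth/length filters", stacklevel=2)
        return pd.Series(dtype=float)
    labels = []
    for taxa in passing["gene_taxa"]:
        if isinstance(taxa, str):
            gene_paths = [t for t in taxa.split(",") if t.strip()]
        else:
            gene_paths = list(taxa)
        cons = contig_consensus_taxonomy(gene_paths, majority_threshold)
        labels.append(cons[-1] if cons else "unclassified")
    cov = passing["coverage"].to_numpy(dtype=float)
    total = cov.sum()
    out = pd.Series(cov, index=labels).groupby(level=0).sum() / total
    return out.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# depth trend statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthTrendResult:
    """One-way ANOVA across depth regions with Tukey HSD pairwise follow-up."""

    f_statistic: float
    pvalue: float
    pairwise: pd.DataFrame = field(repr=False)  # columns group_a, group_b, p_adj


def depth_trend_test(
    values: Sequence[float], labels: Sequence[str]
) -> DepthTrendResult:
    """One-way ANOVA of per-sample ratios across region labels, plus Tukey HSD.

    Regions with fewer than two samples are excluded with a warning; at least
    two usable regions are required. When every value is identical the test
    is degenerate and reported as p = 1 with a warning.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "label": list(labels)})
    groups, names = [], []
    for name, grp in df.groupby("label", sort=True):
        if len(grp) < 2:
            warnings.warn(f"region {name!r} has < 2 samples; excluded", stacklevel=2)
            continue
        groups.append(grp["value"].to_numpy())
        names.append(name)
    if len(groups) < 2:
        raise ValueError("need at least 2 regions with >= 2 samples each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; ANOVA degenerate, p = 1", stacklevel=2)
        empty = pd.DataFrame(columns=["group_a", "group_b", "p_adj"])
        return DepthTrendResult(f_statistic=0.0, pvalue=1.0, pairwise=empty)
    f, p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {"group_a": names[i], "group_b": names[j], "p_adj": float(tukey.pvalue[i, j])}
            )
    return DepthTrendResult(
        f_statistic=float(f), pvalue=float(p), pairwise=pd.DataFrame(rows)
    )
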
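"""Synthetic input tables with the statistical structure the pipeline assumes.

Every table the analysis consumes — per-cell nanoSIMS ion ratios, 15N-NOx
incubation time series, gene-level mapping summaries with contig taxonomy,
and depth profiles of cell density — can be generated here under a fixed
seed, so the full chain is testable without any cruise data.

The generators invert the analysis models: labeled cells are placed at the
ion ratio implied by a drawn Ka, the incubation time and the substrate label
fraction; incubation series grow excess 15N-NOx linearly at the planted rate;
gene read counts are multinomial over gene copies weighted by genome
abundance, gene length and copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nitrification import AIR_N2_RATIO
from .sip import (
    LabelingContext,
    atom_fraction_to_ratio_13C,
    atom_fraction_to_ratio_15N,
    substrate_label_fraction,
)

__all__ = [
    "SipSimParams",
    "NitrifSimParams",
    "MetagSimParams",
    "generate_roi_table",
    "generate_incubation_series",
    "generate_gene_coverage",
    "generate_depth_profile",
    "write_demo_dataset",
]

_LABEL_PURITY = {"urea": 0.98, "ammonium": 0.99}
_N_PER_MOLECULE = {"urea": 2, "ammonium": 1}

#: Taxa planted on ureC-carrying contigs (GTDB-style two-rank paths), with
#: sampling weights loosely following deep-sea ureC-community composition.
_PLANTED_TAXA = (
    ("Archaea;Nitrososphaerota", 0.45),
    ("Bacteria;Proteobacteria", 0.30),
    ("Bacteria;Verrucomicrobiota", 0.10),
    ("Bacteria;Planctomycetota", 0.10),
    ("Bacteria;Nitrospinota", 0.05),
)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


# ---------------------------------------------------------------------------
# nanoSIMS ROI tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SipSimParams:
    """Conditions of one simulated SIP incubation experiment.

    Active cells draw their growth-equivalent label uptake Ka (per day) from
    a lognormal with arithmetic mean ``ka_mean`` and SD ``ka_sd``; inactive
    cells have Ka = 0. Ion-ratio measurement noise is Gaussian on the ratio
    scale with coefficient of variation ``baseline_cv``.
    """

    n_cells_per_depth: int = 100
    frac_active: float = 0.5
    ka_mean: float = 0.05  # d^-1
    ka_sd: float = 0.03
    baseline_ratio_15N: float = AIR_N2_RATIO
    baseline_cv: float = 0.05
    substrate: str = "urea"
    amendment_nM: float = 50.0
    label_purity: float | None = None  # default by substrate: 0.98 urea, 0.99 ammonium
    ambient_nM: float = 50.0
    incubation_h: float = 72.0
    depths_m: Sequence[float] = (50.0, 150.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0)
    site: str = "OO"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.frac_active <= 1.0):
            raise ValueError("frac_active must be in [0, 1]")
        if self.ka_sd < 0:
            raise ValueError("ka_sd must be non-negative")
        if self.amendment_nM < 0 or self.ambient_nM < 0:
            raise ValueError("concentrations must be non-negative")
        if self.substrate not in _LABEL_PURITY:
            raise ValueError(f"unknown substrate {self.substrate!r}")

    @property
    def purity(self) -> float:
        return _LABEL_PURITY[self.substrate] if self.label_purity is None else self.label_purity

    def labeling_context(self) -> LabelingContext:
        """The 15N labeling context implied by these conditions."""
        return LabelingContext(
            amendment_nM=self.amendment_nM,
            label_purity=self.purity,
            ambient_nM=self.ambient_nM,
            incubation_h=self.incubation_h,
            n_per_molecule=_N_PER_MOLECULE[self.substrate],
        )


def generate_roi_table(params: SipSimParams) -> pd.DataFrame:
    """Per-ROI ion-ratio table for 0-h controls and labeled-timepoint cells.

    At each depth, ``n_cells_per_depth`` cells are drawn at 0 h around the
    natural-abundance baseline and another ``n_cells_per_depth`` at the
    labeled timepoint, of which a ``frac_active`` subset carries the elevated
    ratio implied by its Ka draw (capped at full substrate labeling).
    Deterministic under a fixed seed.
    """
    if params.n_cells_per_depth <= 0:
        raise ValueError("n_cells_per_depth must be positive")
    rng = np.random.default_rng(params.seed)
    ctx = params.labeling_context()
    x_sub = substrate_label_fraction(ctx)
    x0 = params.baseline_ratio_15N / (1.0 + params.baseline_ratio_15N)
    t_d = params.incubation_h / 24.0
    n = params.n_cells_per_depth
    n_active = int(round(params.frac_active * n))
    rows = []
    for depth in params.depths_m:
        for timepoint in (0.0, params.incubation_h):
            ka = np.zeros(n)
            if timepoint > 0 and n_active > 0 and params.ka_mean > 0:
                if params.ka_sd > 0:
                    mu, sigma = _lognormal_params(params.ka_mean, params.ka_sd)
                    ka_active = rng.lognormal(mu, sigma, size=n_active)
                else:
                    ka_active = np.full(n_active, params.ka_mean)
                idx = rng.permutation(n)[:n_active]
                ka[idx] = ka_active
            frac_replaced = np.minimum(ka * t_d, 1.0)
            x_cell = x0 + frac_replaced * (x_sub - x0)
            r_true = atom_fraction_to_ratio_15N(x_cell)
            r15 = r_true * (1.0 + params.baseline_cv * rng.standard_normal(n))
            r15 = np.clip(r15, 0.0, None)
            # 13C channel: urea carries one labeled C assimilated with the
            # same Ka; ammonium incubations stay at natural 13C abundance
            if params.substrate == "urea":
                ctx13 = LabelingContext(
                    amendment_nM=params.amendment_nM,
                    label_purity=0.99,
                    ambient_nM=params.ambient_nM,
                    natural_atom_fraction=0.0107,
                    incubation_h=params.incubation_h,
                    n_per_molecule=1,
                )
                x13 = 0.0107 + frac_replaced * (substrate_label_fraction(ctx13) - 0.0107)
            else:
                x13 = np.full(n, 0.0107)
            r13 = atom_fraction_to_ratio_13C(x13)
            r13 = np.clip(r13 * (1.0 + params.baseline_cv * rng.standard_normal(n)), 0.0, None)
            for i in range(n):
                rows.append(
                    {
                        "roi_id": f"{params.site}_{depth:g}m_{timepoint:g}h_{params.substrate}_{i}",
                        "site": params.site,
                        "depth_m": depth,
                        "substrate": params.substrate,
                        "timepoint_h": timepoint,
                        "ratio_15N": r15[i],
                        "ratio_13C": r13[i],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nitrification incubation series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NitrifSimParams:
    """Conditions of one simulated 15N-NOx incubation time series."""

    true_rate: float = 16.0  # nmol N L^-1 d^-1 total N oxidation
    nox_uM: float = 30.0
    timepoints_h: Sequence[float] = (0.0, 24.0, 72.0)
    n_replicates: int = 2
    noise_sd_delta: float = 0.2  # permil, IRMS-scale noise
    substrate_label_fraction: float = 0.5
    substrate: str = "ammonium"
    site: str = "OO"
    depth_m: float = 150.0
    seed: int = 0

    def __post_init__(self):
        t = list(self.timepoints_h)
        if t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must start at 0 and strictly increase")
        if self.noise_sd_delta < 0:
            raise ValueError("noise_sd_delta must be non-negative")
        if not (0.0 < self.substrate_label_fraction <= 1.0):
            raise ValueError("substrate_label_fraction must be in (0, 1]")


def generate_incubation_series(params: NitrifSimParams) -> pd.DataFrame:
    """Replicate delta-15N-NOx time series with a planted oxidation rate.

    Excess 15N-NOx grows linearly at ``true_rate * substrate_label_fraction``
    (nmol 15N L^-1 d^-1); the delta values are back-computed from the implied
    atom fractions with additive Gaussian noise, independent across
    replicates and timepoints.
    """
    if params.nox_uM <= 0:
        raise ValueError("nox_uM must be positive (delta undefined otherwise)")
    rng = np.random.default_rng(params.seed)
    x0 = AIR_N2_RATIO / (1.0 + AIR_N2_RATIO)
    rows = []
    for rep in range(params.n_replicates):
        for t_h in params.timepoints_h:
            excess = params.true_rate * params.substrate_label_fraction * (t_h / 24.0)
            x_t = x0 + excess / (params.nox_uM * 1000.0)
            r = x_t / (1.0 - x_t)
            delta = (r / AIR_N2_RATIO - 1.0) * 1000.0
            if params.noise_sd_delta > 0:
                delta += rng.normal(0.0, params.noise_sd_delta)
            rows.append(
                {
                    "site": params.site,
                    "depth_m": params.depth_m,
                    "substrate": params.substrate,
                    "replicate_id": f"rep{rep + 1}",
                    "timepoint_h": t_h,
                    "delta15N_NOx_permil": delta,
                    "nox_uM": params.nox_uM,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagenome gene-coverage tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetagSimParams:
    """Conditions of a simulated marker-gene mapping summary.

    Every genome carries exactly one recA; a ``frac_ureC`` subset carries
    ureC with mean copy number ``ureC_copy_mean`` per carrier; a
    ``frac_amoA`` subset (drawn from the ureC carriers first, emulating
    ammonia-oxidizer urease) carries one amoA. Genome relative abundances
    are lognormal with shape ``abundance_sigma``.
    """

    n_genomes: int = 500
    frac_ureC: float = 0.39
    ureC_copy_mean: float = 1.1
    frac_amoA: float = 0.2
    gene_length_bp: Mapping[str, int] = field(
        default_factory=lambda: {"ureC": 1707, "recA": 1041, "amoA": 651}
    )
    library_reads: int = 1_000_000
    depth_labels: Sequence[str] = ("50m", "150m", "500m", "1000m", "2000m", "3000m", "4000m")
    abundance_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.frac_ureC <= 1.0):
            raise ValueError("frac_ureC must be in [0, 1]")
        if any(length <= 0 for length in self.gene_length_bp.values()):
            raise ValueError("gene lengths must be positive")
        if self.ureC_copy_mean < 1.0:
            raise ValueError("carrier genomes have at least one ureC copy")


def generate_gene_coverage(params: MetagSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(gene coverage table, contig gene-taxonomy hits table).

    Read counts are multinomial over all marker-gene copies with weights
    genome abundance x gene length x copy number, so the planted carrier
    fraction is recoverable from the copy-corrected ureC/recA RPKM ratio.
    Each ureC carrier contributes one contig with planted gene-level
    taxonomy labels, coverage proportional to abundance, and a drawn breadth.
    """
    if params.library_reads <= 0:
        raise ValueError("library_reads must be positive")
    rng = np.random.default_rng(params.seed)
    cov_rows, contig_rows = [], []
    taxa = [t for t, _ in _PLANTED_TAXA]
    taxa_w = np.array([w for _, w in _PLANTED_TAXA])
    taxa_w = taxa_w / taxa_w.sum()
    n = params.n_genomes
    n_carriers = int(round(params.frac_ureC * n))
    for sample in params.depth_labels:
        abundance = rng.lognormal(0.0, params.abundance_sigma, size=n)
        carriers = rng.permutation(n)[:n_carriers]
        is_carrier = np.zeros(n, dtype=bool)
        is_carrier[carriers] = True
        # integer + Bernoulli fractional part -> mean copy = ureC_copy_mean
        base = int(np.floor(params.ureC_copy_mean))
        extra_p = params.ureC_copy_mean - base
        copies = np.zeros(n, dtype=int)
        copies[is_carrier] = base + (rng.random(n_carriers) < extra_p)
        amoa = np.zeros(n, dtype=bool)
        n_amoa = int(round(params.frac_amoA * n))
        # prefer ureC carriers as amoA hosts (archaeal nitrifiers often have both)
        order = np.concatenate([rng.permutation(carriers), rng.permutation(np.where(~is_carrier)[0])])
        amoa[order[:n_amoa]] = True
        genome_taxon = rng.choice(len(taxa), size=n, p=taxa_w)

        instances = []  # (genome index, gene, weight)
        lengths = params.gene_length_bp
        for i in range(n):
            instances.append((i, "recA", abundance[i] * lengths["recA"]))
            if copies[i] > 0:
                instances.append((i, "ureC", abundance[i] * lengths["ureC"] * copies[i]))
            if amoa[i] and "amoA" in lengths:
                instances.append((i, "amoA", abundance[i] * lengths["amoA"]))
        weights = np.array([w for _, _, w in instances])
        reads = rng.multinomial(params.library_reads, weights / weights.sum())
        for (i, gene, _), nreads in zip(instances, reads):
            contig_id = f"{sample}_g{i}"
            cov_rows.append(
                {
                    "sample_id": sample,
                    "gene": gene,
                    "contig_id": contig_id,
                    "mapped_reads": int(nreads),
                    "gene_length_bp": lengths[gene],
                    "library_mapped_reads": params.library_reads,
                    "breadth": float(np.clip(rng.uniform(0.8, 1.0), 0.0, 1.0))
                    if nreads > 0
                    else 0.0,
                }
            )
        # one ureC-bearing contig per carrier genome
        for i in carriers:
            taxon = taxa[genome_taxon[i]]
            n_genes = int(rng.integers(3, 6))
            gene_taxa = [taxon] * n_genes
            if rng.random() < 0.15:  # occasional discordant gene call
                other = taxa[rng.choice([k for k in range(len(taxa)) if k != genome_taxon[i]])]
                gene_taxa[-1] = other
            length = int(rng.integers(1500, 3000)) if rng.random() < 0.1 else int(
                rng.integers(3000, 20000)
            )
            breadth = float(rng.uniform(0.2, 0.5)) if rng.random() < 0.1 else float(
                rng.uniform(0.55, 1.0)
            )
            contig_rows.append(
                {
                    "contig_id": f"{sample}_g{i}",
                    "sample_id": sample,
                    "length_bp": length,
                    "gene_taxa": ",".join(gene_taxa),
                    "coverage": float(abundance[i] * params.library_reads / 1e6),
                    "breadth": breadth,
                }
            )
    return pd.DataFrame(cov_rows), pd.DataFrame(contig_rows)


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def generate_depth_profile(
    depths_m: Sequence[float] = (50.0, 150.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0),
    surface_density_per_L: float = 5e8,
    efolding_m: float = 800.0,
    floor_per_L: float = 2e7,
) -> pd.DataFrame:
    """Cell-density depth profile: exponential decline to a deep-sea floor.

    Defaults emulate typical open-ocean prokaryote counts (~5e8 cells/L near
    the surface falling to a few 1e7 cells/L in the bathypelagic).
    """
    depths = np.asarray(depths_m, dtype=float)
    density = floor_per_L + (surface_density_per_L - floor_per_L) * np.exp(-depths / efolding_m)
    return pd.DataFrame({"depth_m": depths, "cells_per_L": density})


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def write_demo_dataset(outdir, seed: int = 0, n_cells_per_depth: int = 100) -> dict[str, str]:
    """Write a complete small demo dataset (two sites, seven depths) as TSVs.

    Returns a mapping of table name to file path. Nitrification series are
    generated for depths below 50 m with rates declining with depth, the
    steepest at 150 m, emulating the depth structure of upper-ocean
    nitrification.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    depths = (50.0, 150.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0)

    roi_frames = []
    for k, site in enumerate(("OO", "SL")):
        for substrate, ka_mean in (("urea", 0.06), ("ammonium", 0.04)):
            roi_frames.append(
                generate_roi_table(
                    SipSimParams(
                        n_cells_per_depth=n_cells_per_depth,
                        frac_active=0.4 if site == "SL" else 0.3,
                        ka_mean=ka_mean,
                        ka_sd=0.03,
                        substrate=substrate,
                        depths_m=depths,
                        site=site,
                        seed=int(rng.integers(2**31)),
                    )
                )
            )
    roi = pd.concat(roi_frames, ignore_index=True)

    nitrif_frames = []
    rate_by_depth = {150.0: 16.0, 500.0: 1.6, 1000.0: 1.2, 2000.0: 1.0, 3000.0: 1.4, 4000.0: 0.8}
    for site, scale in (("OO", 0.4), ("SL", 1.0)):
        for substrate in ("ammonium", "urea"):
            for depth, rate in rate_by_depth.items():
                if site == "OO" and depth == 4000.0:
                    continue
                nitrif_frames.append(
                    generate_incubation_series(
                        NitrifSimParams(
                            true_rate=rate * scale * (0.75 if substrate == "urea" else 1.0),
                            substrate=substrate,
                            site=site,
                            depth_m=depth,
                            seed=int(rng.integers(2**31)),
                        )
                    )
                )
    nitrif = pd.concat(nitrif_frames, ignore_index=True)

    coverage, contigs = generate_gene_coverage(
        MetagSimParams(
            n_genomes=300,
            library_reads=200_000,
            depth_labels=tuple(f"OO_{d:g}m" for d in depths),
            seed=int(rng.integers(2**31)),
        )
    )
    profile = generate_depth_profile(depths)

    paths = {}
    for name, df in (
        ("roi", roi),
        ("nitrif", nitrif),
        ("gene_coverage", coverage),
        ("contig_hits", contigs),
        ("profile", profile),
    ):
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)
    return paths
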
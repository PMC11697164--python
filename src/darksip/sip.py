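"""Single-cell stable-isotope-probing (SIP) calculations from nanoSIMS ion ratios.

Converts per-cell (per region-of-interest) secondary-ion ratios measured by
nanoSIMS into isotope atom fractions, enrichment calls against unlabeled 0-h
controls, isotope-based growth coefficients (Ka), per-cell elemental
assimilation rates, depth-level summaries, and water-column-region-integrated
assimilation.

The mass-balance model is linear: a cell that replaces a fraction ``f`` of its
initial element pool with substrate-derived atoms during the incubation has an
atom fraction ``x_cell = x0 + f * (x_sub - x0)``, where ``x0`` is the
unlabeled baseline and ``x_sub`` the atom fraction of the amended substrate
pool. Ka is that replacement fraction per day.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NATURAL_15N_ATOM_FRACTION",
    "NATURAL_13C_ATOM_FRACTION",
    "REGION_BOUNDS_M",
    "REGION_NAMES",
    "ControlBaseline",
    "LabelingContext",
    "SubstrateComparison",
    "ratio_to_atom_fraction_15N",
    "ratio_to_atom_fraction_13C",
    "atom_fraction_to_ratio_15N",
    "atom_fraction_to_ratio_13C",
    "compute_baseline",
    "call_enrichment",
    "substrate_label_fraction",
    "compute_ka",
    "compute_assimilation_rate",
    "process_roi_table",
    "summarize_depth",
    "assign_region",
    "integrate_region",
    "compare_substrates",
]

#: Natural abundance of 15N (atom fraction) and of 13C.
NATURAL_15N_ATOM_FRACTION = 0.003663
NATURAL_13C_ATOM_FRACTION = 0.0107

#: Depth-zone edges in meters below surface: epi- [0, 200), meso- [200, 1000),
#: bathypelagic [1000, 4500).
REGION_BOUNDS_M = (0.0, 200.0, 1000.0, 4500.0)
REGION_NAMES = ("epipelagic", "mesopelagic", "bathypelagic")


# ---------------------------------------------------------------------------
# ion-ratio <-> atom-fraction algebra
# ---------------------------------------------------------------------------

def ratio_to_atom_fraction_15N(ratio):
    """Convert a 12C15N-/12C14N- ion ratio to the 15N atom fraction.

    The CN- secondary ion carries one N atom, so the ratio R maps to the
    atom fraction as ``x = R / (1 + R)``.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValueError("ion ratio must be non-negative")
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def ratio_to_atom_fraction_13C(ratio):
    """Convert a 13C12C-/12C2- ion ratio to the 13C atom fraction.

    The C2- dimer carries two C atoms; for atom fraction x the mixed dimer
    occurs with relative frequency 2x(1-x) against (1-x)^2 for 12C2, so
    ``R = 2x / (1 - x)`` and hence ``x = R / (2 + R)``.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValueError("ion ratio must be non-negative")
    out = r / (2.0 + r)
    return out if out.ndim else float(out)


def atom_fraction_to_ratio_15N(x):
    """Inverse of :func:`ratio_to_atom_fraction_15N` (x in [0, 1))."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise ValueError("atom fraction must lie in [0, 1)")
    out = x / (1.0 - x)
    return out if out.ndim else float(out)


def atom_fraction_to_ratio_13C(x):
    """Inverse of :func:`ratio_to_atom_fraction_13C` (x in [0, 1))."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise ValueError("atom fraction must lie in [0, 1)")
    out = 2.0 * x / (1.0 - x)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# baseline and enrichment calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlBaseline:
    """Mean/SD of the unlabeled 0-h control cells for one site and substrate."""

    site: str
    substrate: str
    isotope: str  # "15N" or "13C"
    mean_ratio: float
    sd_ratio: float
    n_cells: int


_ISOTOPE_COLUMN = {"15N": "ratio_15N", "13C": "ratio_13C"}


def compute_baseline(
    rois: pd.DataFrame, site: str, substrate: str, isotope: str = "15N"
) -> ControlBaseline:
    """Mean and sample SD (n-1) of the 0-h control ratios for one group.

    Raises ``ValueError`` if fewer than two control cells are available.
    """
    col = _ISOTOPE_COLUMN[isotope]
    grp = rois[
        (rois["site"] == site)
        & (rois["substrate"] == substrate)
        & (rois["timepoint_h"] == 0)
    ][col].dropna()
    if len(grp) < 2:
        raise ValueError(
            f"insufficient 0-h baseline cells for {site}/{substrate}/{isotope}: "
            f"need >= 2, got {len(grp)}"
        )
    return ControlBaseline(
        site=site,
        substrate=substrate,
        isotope=isotope,
        mean_ratio=float(grp.mean()),
        sd_ratio=float(grp.std(ddof=1)),
        n_cells=int(len(grp)),
    )


def call_enrichment(ratio, baseline: ControlBaseline):
    """True iff the measured ratio exceeds baseline mean + 2 SD (strict)."""
    r = np.asarray(ratio, dtype=float)
    out = r > baseline.mean_ratio + 2.0 * baseline.sd_ratio
    return out if out.ndim else bool(out)


# ---------------------------------------------------------------------------
# labeling context and rate algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelingContext:
    """Isotope-label bookkeeping for one amended substrate pool.

    ``n_per_molecule`` is the number of atoms of the traced element per
    substrate molecule (urea N = 2, ammonium N = 1, urea C = 1); molecule
    concentrations are converted to element-atom concentrations before the
    pools are mixed.
    """

    amendment_nM: float = 50.0
    label_purity: float = 0.98
    ambient_nM: float = 0.0
    natural_atom_fraction: float = NATURAL_15N_ATOM_FRACTION
    incubation_h: float = 72.0
    n_per_molecule: int = 2

    def __post_init__(self):
        if not (0.0 <= self.label_purity <= 1.0):
            raise ValueError("label_purity must be in [0, 1]")
        if not (0.0 <= self.natural_atom_fraction <= 1.0):
            raise ValueError("natural_atom_fraction must be in [0, 1]")
        if self.amendment_nM < 0 or self.ambient_nM < 0:
            raise ValueError("concentrations must be non-negative")


def substrate_label_fraction(ctx: LabelingContext) -> float:
    """Atom fraction of the mixed (amended + ambient) substrate pool.

    Element-atom weighted mean of the label purity and the natural abundance
    of the ambient pool.
    """
    atoms_amend = ctx.amendment_nM * ctx.n_per_molecule
    atoms_ambient = ctx.ambient_nM * ctx.n_per_molecule
    total = atoms_amend + atoms_ambient
    if total <= 0:
        raise ValueError("total substrate pool is zero; label fraction undefined")
    return (atoms_amend * ctx.label_purity + atoms_ambient * ctx.natural_atom_fraction) / total


def compute_ka(x_cell, x0: float, x_sub: float, t_h: float):
    """Isotope-based growth coefficient Ka (per day).

    ``Ka = (x_cell - x0) / ((x_sub - x0) * t_days)`` — the fraction of the
    cell's initial element content replaced by substrate-derived atoms per
    day, under linear (non-compounding) uptake. Negative excess (measurement
    noise below baseline) clamps to 0 with a warning.
    """
    if t_h <= 0:
        raise ValueError("incubation time must be positive")
    contrast = x_sub - x0
    if contrast <= 0:
        raise ValueError("no label contrast: substrate atom fraction must exceed baseline")
    t_d = t_h / 24.0
    ka = (np.asarray(x_cell, dtype=float) - x0) / (contrast * t_d)
    if np.any(ka < 0):
        warnings.warn("negative atom-fraction excess clamped to Ka = 0", stacklevel=2)
        ka = np.clip(ka, 0.0, None)
    return ka if ka.ndim else float(ka)


def compute_assimilation_rate(ka, cell_content_fg: float):
    """Per-cell assimilation rate in fg element cell^-1 h^-1.

    ``rate = Ka [d^-1] * cell element content [fg] / 24``.
    """
    if cell_content_fg < 0:
        raise ValueError("cell content must be non-negative")
    ka = np.asarray(ka, dtype=float)
    if np.any(ka < 0):
        raise ValueError("Ka must be non-negative")
    out = ka * cell_content_fg / 24.0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# table-level processing
# ---------------------------------------------------------------------------

def process_roi_table(
    rois: pd.DataFrame,
    contexts: Mapping[str, LabelingContext],
    cell_content_fg: float,
    isotope: str = "15N",
) -> pd.DataFrame:
    """Per-cell enrichment, Ka and rate for every labeled-timepoint ROI.

    Baselines are computed per (site, substrate) from that group's 0-h cells.
    ``contexts`` maps substrate name to its :class:`LabelingContext`.
    Returns one row per ROI with timepoint > 0.
    """
    col = _ISOTOPE_COLUMN[isotope]
    to_x = ratio_to_atom_fraction_15N if isotope == "15N" else ratio_to_atom_fraction_13C
    out = []
    for (site, substrate), grp in rois.groupby(["site", "substrate"], sort=True):
        ctx = contexts[substrate]
        baseline = compute_baseline(rois, site, substrate, isotope)
        x0 = to_x(baseline.mean_ratio)
        x_sub = substrate_label_fraction(ctx)
        labeled = grp[grp["timepoint_h"] > 0]
        if labeled.empty:
            continue
        ratios = labeled[col].to_numpy(dtype=float)
        enriched = call_enrichment(ratios, baseline)
        x_cell = to_x(ratios)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # bulk processing: clamps expected
            ka = np.array(
                [compute_ka(x, x0, x_sub, t) for x, t in zip(x_cell, labeled["timepoint_h"])]
            )
        rate = compute_assimilation_rate(ka, cell_content_fg)
        out.append(
            pd.DataFrame(
                {
                    "roi_id": labeled["roi_id"].to_numpy(),
                    "site": site,
                    "depth_m": labeled["depth_m"].to_numpy(),
                    "substrate": substrate,
                    "timepoint_h": labeled["timepoint_h"].to_numpy(),
                    "enriched": enriched,
                    "atom_fraction": x_cell,
                    "atom_fraction_excess": x_cell - x0,
                    "ka_per_day": ka,
                    "rate_fg_per_cell_h": rate,
                }
            )
        )
    if not out:
        raise ValueError("no labeled-timepoint cells in input")
    return pd.concat(out, ignore_index=True)


def summarize_depth(results: pd.DataFrame) -> pd.DataFrame:
    """Per site/depth/substrate summary of the per-cell results.

    ``pct_enriched`` is 100 * enriched / analyzed; mean Ka and rate are taken
    over enriched cells only and reported as NaN when no cell is enriched.
    """
    if results.empty:
        raise ValueError("empty per-cell results")
    rows = []
    for (site, depth, substrate), grp in results.groupby(
        ["site", "depth_m", "substrate"], sort=True
    ):
        enr = grp[grp["enriched"]]
        rows.append(
            {
                "site": site,
                "depth_m": depth,
                "substrate": substrate,
                "n_cells": len(grp),
                "pct_enriched": 100.0 * len(enr) / len(grp),
                "mean_rate_enriched": float(enr["rate_fg_per_cell_h"].mean())
                if len(enr)
                else np.nan,
                "mean_ka_enriched": float(enr["ka_per_day"].mean()) if len(enr) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def assign_region(depth_m: float, bounds: Sequence[float] = REGION_BOUNDS_M) -> str:
    """Map a depth to its water-column region using half-open [lo, hi) bins."""
    if not (bounds[0] <= depth_m < bounds[-1]):
        raise ValueError(f"depth {depth_m} m outside region bounds {bounds}")
    return REGION_NAMES[bisect_right(bounds, depth_m) - 1]


def integrate_region(
    summaries: pd.DataFrame,
    cell_density: Mapping[float, float],
    region_volume_L: Mapping[str, float],
    bounds: Sequence[float] = REGION_BOUNDS_M,
) -> pd.DataFrame:
    """Region-integrated assimilation from depth summaries and cell densities.

    Per-depth volumetric rate (fg L^-1 h^-1) is cell density times the
    enriched fraction times the mean per-cell rate of enriched cells; the
    region total (fg h^-1) is the arithmetic mean of the volumetric rates of
    depths falling in the region times the region volume. Regions without a
    sampled depth are reported as NaN with a warning.
    """
    vol_rows = []
    for _, row in summaries.iterrows():
        depth = float(row["depth_m"])
        density = cell_density[depth]
        mean_rate = row["mean_rate_enriched"]
        frac = row["pct_enriched"] / 100.0
        volumetric = 0.0 if frac == 0 else density * frac * float(mean_rate)
        vol_rows.append(
            {
                "region": assign_region(depth, bounds),
                "depth_m": depth,
                "volumetric_rate_fg_L_h": volumetric,
            }
        )
    voldf = pd.DataFrame(vol_rows)
    out = []
    for region in REGION_NAMES:
        sub = voldf[voldf["region"] == region]
        if sub.empty:
            warnings.warn(f"no sampled depth in region {region!r}", stacklevel=2)
            total = np.nan
            mean_vol = np.nan
        else:
            mean_vol = float(sub["volumetric_rate_fg_L_h"].mean())
            total = mean_vol * region_volume_L[region]
        out.append(
            {
                "region": region,
                "mean_volumetric_rate_fg_L_h": mean_vol,
                "total_rate_fg_h": total,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# substrate comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstrateComparison:
    """Two-sided rank-sum comparison of two samples of per-cell rates."""

    statistic: float
    pvalue: float
    significant: bool


def compare_substrates(
    rates_a: Iterable[float], rates_b: Iterable[float], alpha: float = 0.05
) -> SubstrateComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) on unpaired per-cell rates.

    Single cells from separate incubations cannot be paired, so the unpaired
    form is used. The exact null distribution is used when the samples are
    free of ties. Fully degenerate (all-tied) input yields p = 1 with a
    warning.
    """
    a = np.asarray(list(rates_a), dtype=float)
    b = np.asarray(list(rates_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; comparison is degenerate", stacklevel=2)
        return SubstrateComparison(statistic=len(a) * len(b) / 2.0, pvalue=1.0, significant=False)
    method = "exact" if len(np.unique(pooled)) == len(pooled) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return SubstrateComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )
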
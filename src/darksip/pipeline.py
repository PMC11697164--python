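"""Pipeline orchestration: generator -> SIP -> nitrification -> genes -> budget.

One declarative config drives every stage; all constants the analysis needs
(label purities, natural abundances, marker copy number, fixation yield,
per-cell elemental content, region bounds) live in the config with
documented defaults. Runs are deterministic for a fixed config and seed and
every stage writes its table under the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import budget as budget_mod
from . import genes as genes_mod
from . import nitrification as nitrif_mod
from . import sip as sip_mod
from . import synthetic, validate

__all__ = ["DEFAULT_CONFIG", "StageError", "load_config", "run_pipeline"]

log = logging.getLogger("darksip")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "darksip_out",
    "constants": {
        "copy_number": 1.1,  # mean ureC copies per carrier genome
        "yield_molC_per_molN": 0.09,
        # per-cell N content is a placeholder (not constrained by the study
        # design); override with a site-appropriate value
        "cell_content_fg_N": 10.0,
        "alpha": 0.05,
        "nox_floor_uM": 0.5,  # series below this mean NOx are excluded
        "region_bounds_m": [0.0, 200.0, 1000.0, 4500.0],
        "region_volumes_L": {
            "epipelagic": 1.0e18,
            "mesopelagic": 4.0e18,
            "bathypelagic": 1.0e19,
        },
        "label": {
            "urea": {
                "amendment_nM": 50.0,
                "label_purity": 0.98,
                "ambient_nM": 50.0,
                "n_per_molecule": 2,
            },
            "ammonium": {
                "amendment_nM": 50.0,
                "label_purity": 0.99,
                "ambient_nM": 10.0,
                "n_per_molecule": 1,
            },
        },
    },
    "environment": {
        "sst_C": 12.0,
        "npp_mgC_m2_d": 500.0,
        "z_top_m": 100.0,
        "z_bottom_m": 4000.0,
    },
    "inputs": {"synthetic": {}},
}


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path) -> dict:
    """Read a YAML config and merge it over the documented defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _deep_merge(DEFAULT_CONFIG, user)
    if "inputs" in user:
        # input blocks are declarative alternatives, never merged with defaults
        cfg["inputs"] = user["inputs"]
    if "synthetic" not in cfg["inputs"]:
        for name, block in cfg["inputs"].items():
            if "path" in block and not Path(block["path"]).exists():
                raise FileNotFoundError(f"input {name!r}: {block['path']} does not exist")
    return cfg


def _config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _contexts(config: dict) -> dict[str, sip_mod.LabelingContext]:
    return {
        name: sip_mod.LabelingContext(**block)
        for name, block in config["constants"]["label"].items()
    }


def _load_inputs(config: dict, outdir: Path) -> dict[str, pd.DataFrame]:
    blocks = config["inputs"]
    if "synthetic" in blocks:
        gen = dict(blocks["synthetic"])
        gen.setdefault("seed", config["seed"])
        paths = synthetic.write_demo_dataset(outdir / "inputs", **gen)
        names = {"roi": "roi", "nitrif": "nitrif", "gene_coverage": "gene_coverage",
                 "contig_hits": "contig_hits", "profile": "profile"}
        return {k: pd.read_csv(paths[v], sep="\t") for k, v in names.items()}
    return {name: pd.read_csv(block["path"], sep="\t") for name, block in blocks.items()}


def _depth_from_sample(sample_id: str) -> float | None:
    m = re.search(r"(\d+(?:\.\d+)?)m$", str(sample_id))
    return float(m.group(1)) if m else None


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return str(path)


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute every stage and return the run report (also written as JSON).

    Stage order: input generation/loading and validation, single-cell SIP,
    nitrification rates, gene prevalence, carbon budget, report assembly.
    Any stage failure raises :class:`StageError` naming the stage.
    """
    outdir = Path(output_dir or config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    consts = config["constants"]
    alpha = consts["alpha"]
    tables: dict[str, str] = {}
    comparisons: dict = {}

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        log.info("stage=%s loading inputs", stage)
        data = _load_inputs(config, outdir)
        issues = validate.validate_tables(data)
        errors = [i for i in issues if i.severity == "error"]
        for issue in issues:
            log.warning("validation %s: %s row=%s %s", issue.severity, issue.table,
                        issue.row, issue.message)
        if errors:
            raise ValueError(f"{len(errors)} validation errors (first: {errors[0]})")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- single-cell SIP -------------------------------------------------
    stage = "sip"
    try:
        log.info("stage=%s per-cell rates", stage)
        contexts = _contexts(config)
        cells = sip_mod.process_roi_table(
            data["roi"], contexts, cell_content_fg=consts["cell_content_fg_N"]
        )
        summaries = sip_mod.summarize_depth(cells)
        tables["sip_cells"] = _write(cells, outdir / "sip_cells.tsv")
        tables["sip_depth_summary"] = _write(summaries, outdir / "sip_depth_summary.tsv")

        density = dict(
            zip(data["profile"]["depth_m"].astype(float), data["profile"]["cells_per_L"])
        )
        region_frames = []
        for site, site_sum in summaries.groupby("site"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reg = sip_mod.integrate_region(
                    site_sum,
                    density,
                    consts["region_volumes_L"],
                    bounds=consts["region_bounds_m"],
                )
            reg.insert(0, "site", site)
            region_frames.append(reg)
        tables["sip_region_integration"] = _write(
            pd.concat(region_frames, ignore_index=True), outdir / "sip_region_integration.tsv"
        )

        sub_rows = []
        for (site, depth), grp in cells.groupby(["site", "depth_m"]):
            urea = grp[(grp["substrate"] == "urea") & grp["enriched"]]["rate_fg_per_cell_h"]
            ammo = grp[(grp["substrate"] == "ammonium") & grp["enriched"]]["rate_fg_per_cell_h"]
            if len(urea) < 3 or len(ammo) < 3:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_res = sip_mod.compare_substrates(urea, ammo, alpha=alpha)
            sub_rows.append(
                {"site": site, "depth_m": depth, "statistic": cmp_res.statistic,
                 "pvalue": cmp_res.pvalue, "significant": cmp_res.significant}
            )
        comparisons["sip_urea_vs_ammonium"] = sub_rows
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- nitrification ---------------------------------------------------
    stage = "nitrif"
    try:
        log.info("stage=%s rate fits", stage)
        contexts = _contexts(config)
        rate_rows = []
        rep_rates: dict[tuple, dict[str, float]] = {}
        for (site, depth, substrate), grp in data["nitrif"].groupby(
            ["site", "depth_m", "substrate"], sort=True
        ):
            if grp["nox_uM"].mean() < consts["nox_floor_uM"]:
                log.warning("excluding %s/%s/%s: NOx below floor", site, depth, substrate)
                continue
            x_sub = sip_mod.substrate_label_fraction(contexts[substrate])
            res = nitrif_mod.fit_rate(grp, x_sub, alpha=alpha)
            per_rep = nitrif_mod.fit_rate_per_replicate(grp, x_sub, alpha=alpha)
            rep_rates[(site, depth, substrate)] = {r: v.rate for r, v in per_rep.items()}
            rate_rows.append(
                {"site": site, "depth_m": depth, "substrate": substrate,
                 "rate_nmolN_L_d": res.rate, "stderr": res.stderr,
                 "p_slope": res.p_slope, "detected": res.detected,
                 "n_points": res.n_points}
            )
        rates = pd.DataFrame(rate_rows)
        tables["nitrif_rates"] = _write(rates, outdir / "nitrif_rates.tsv")

        t_rows = []
        for (site, depth), _ in rates.groupby(["site", "depth_m"]):
            key_u, key_a = (site, depth, "urea"), (site, depth, "ammonium")
            if key_u in rep_rates and key_a in rep_rates:
                ru, ra = list(rep_rates[key_u].values()), list(rep_rates[key_a].values())
                if len(ru) >= 2 and len(ra) >= 2:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cmp_res = nitrif_mod.compare_rates(ru, ra, alpha=alpha)
                    t_rows.append(
                        {"site": site, "depth_m": depth, "statistic": cmp_res.statistic,
                         "pvalue": cmp_res.pvalue,
                         "indistinguishable": cmp_res.indistinguishable}
                    )
        comparisons["nitrif_urea_vs_ammonium"] = t_rows
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- gene prevalence -------------------------------------------------
    stage = "genes"
    try:
        log.info("stage=%s prevalence", stage)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prev = genes_mod.prevalence_table(
                data["gene_coverage"], copy_number=consts["copy_number"]
            )
        tables["gene_prevalence"] = _write(prev, outdir / "gene_prevalence.tsv")

        relabund_rows = []
        for sample, grp in data["contig_hits"].groupby("sample_id"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frac = genes_mod.ureC_taxon_relabund(grp)
            for taxon, f in frac.items():
                relabund_rows.append({"sample_id": sample, "taxon": taxon, "fraction": f})
        tables["ureC_taxon_composition"] = _write(
            pd.DataFrame(relabund_rows), outdir / "ureC_taxon_composition.tsv"
        )

        depths = prev["sample_id"].map(_depth_from_sample)
        trend = None
        if depths.notna().all():
            bounds = consts["region_bounds_m"]
            labels = [sip_mod.assign_region(d, bounds) for d in depths]
            if pd.Series(labels).value_counts().ge(2).sum() >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = genes_mod.depth_trend_test(prev["ratio_ureC_recA"], labels)
                trend = {"f_statistic": res.f_statistic, "pvalue": res.pvalue,
                         "pairwise": res.pairwise.to_dict(orient="records")}
        comparisons["prevalence_depth_trend"] = trend
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- carbon budget ---------------------------------------------------
    stage = "budget"
    try:
        log.info("stage=%s carbon budget", stage)
        env = config["environment"]
        budget_rows = []
        for site, site_rates in rates.groupby("site"):
            site_env = env.get(site, env) if isinstance(env.get(site, None), dict) else env
            # non-detected rates enter the profile as zero, not missing
            eff = site_rates.assign(
                rate=np.where(site_rates["detected"], site_rates["rate_nmolN_L_d"], 0.0)
            )
            profile = (
                eff.groupby("depth_m")["rate"].sum().sort_index()
            )
            inputs = budget_mod.CarbonBudgetInputs(
                sst_C=site_env["sst_C"],
                npp_mgC_m2_d=site_env["npp_mgC_m2_d"],
                nitrif_profile=list(profile.items()),
                z_top_m=site_env["z_top_m"],
                z_bottom_m=site_env["z_bottom_m"],
                yield_molC_per_molN=consts["yield_molC_per_molN"],
            )
            res = budget_mod.compute_budget(inputs)
            budget_rows.append(
                {"site": site, "e_eff": res.e_eff,
                 "poc_flux_mgC_m2_d": res.poc_flux_mgC_m2_d,
                 "cfix_mgC_m2_d": res.cfix_mgC_m2_d,
                 "pct_of_poc": res.pct_of_poc,
                 "pct_of_poc_rounded": int(round(res.pct_of_poc))}
            )
        tables["carbon_budget"] = _write(pd.DataFrame(budget_rows), outdir / "carbon_budget.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- report ----------------------------------------------------------
    try:
        pkg_version = _pkg_version("darksip")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    report = {
        "tables": tables,
        "comparisons": comparisons,
        "provenance": {
            "config_sha256": _config_hash(config),
            "seed": config["seed"],
            "version": pkg_version,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("report written to %s", outdir / "report.json")
    return report
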
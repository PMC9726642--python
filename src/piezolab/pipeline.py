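"""End-to-end orchestration: simulate → analyze → recover.

``simulate`` writes a synthetic dataset; ``analyze`` runs the full chain
(rates → ratio points → depth power law → conversion fit → single-cell
uptake → activity histograms → piezo classification → carbon budget) on a
dataset directory and writes tabular results plus a markdown report;
``recover`` compares the recovered quantities against the generator truth.
Every run writes a manifest (config snapshot, seed, file digests, timings)
from which the outputs can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .radiotracer import (
    ATMOSPHERIC,
    IN_SITU,
    incubations_from_frame,
    leucine_rate,
    rates_to_frame,
    ratio_points_from_rates,
)
from .pressure import fit_power_law
from .autoradiography import (
    ConversionFit,
    fit_conversion,
    halo_volume,
    cell_uptake,
    paired_histograms,
    highly_active_fraction,
    taxon_paired_test,
    DEFAULT_BIN_WIDTH,
)
from .classification import classify
from .budget import budget_table, CONVERSION_FACTORS
from .synthetic import SyntheticConfig, write_dataset

log = logging.getLogger("piezolab")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(outdir: Path, seed: int | None, config: dict, stages: dict) -> None:
    files = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "stage_seconds": stages,
        "outputs": {p.name: _digest(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def cmd_simulate(config: SyntheticConfig, outdir) -> Path:
    """Generate the synthetic dataset directory (CSV tables + truth + manifest)."""
    out = Path(outdir)
    t0 = time.perf_counter()
    meta = write_dataset(config, out)
    log.info("simulate: seed=%s outdir=%s", config.seed, out)
    from dataclasses import asdict

    cfg = asdict(config)
    cfg["depths"] = list(cfg["depths"])
    cfg["class_fractions"] = list(cfg["class_fractions"])
    cfg["uptake_distribution"] = meta["uptake_distribution"]
    _manifest(out, config.seed, cfg, {"simulate": time.perf_counter() - t0})
    return out


def cmd_analyze(
    dataset_dir,
    outdir,
    cf: tuple[float, ...] = CONVERSION_FACTORS,
    geometry: str = "hemisphere",
    width: float = DEFAULT_BIN_WIDTH,
    cap_at_100: bool = True,
) -> Path:
    """Run the full analysis chain on a dataset directory."""
    ds = Path(dataset_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    def stage(name):
        stages[name] = time.perf_counter()
        log.info("analyze: stage=%s", name)

    def done(name):
        stages[name] = time.perf_counter() - stages[name]

    # --- bulk rates and ratio points -------------------------------------
    stage("rates")
    incs = incubations_from_frame(pd.read_csv(ds / "incubations.csv"))
    rates = [leucine_rate(i) for i in incs]
    rates_to_frame(rates).to_csv(out / "rates.csv", index=False)
    points = ratio_points_from_rates(rates)
    done("rates")

    stage("power_law")
    fit = fit_power_law(points)
    (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    done("power_law")

    # --- single-cell chain ------------------------------------------------
    stage("cells")
    pairs_df = pd.read_csv(ds / "conversion_pairs.csv")
    conv = fit_conversion(
        list(zip(pairs_df["bulk_rate_pmol_l_h"], pairs_df["halo_volume_rate_um3_l_h"]))
    )
    cells = pd.read_csv(ds / "cells.csv")
    vols = cells["halo_area_um2"].map(lambda a: halo_volume(a, geometry))
    uptake = [
        cell_uptake(v, d, conv) for v, d in zip(vols, cells["duration_h"])
    ]
    cells = cells.assign(halo_volume_um3=vols, uptake_amol_d=uptake)
    cells[["cell_id", "condition", "taxon", "uptake_amol_d"]].to_csv(
        out / "cell_uptake.csv", index=False
    )
    done("cells")

    stage("classification")
    active = cells[cells["uptake_amol_d"] > 0]
    u_in = active.loc[active["condition"] == IN_SITU, "uptake_amol_d"]
    u_atm = active.loc[active["condition"] == ATMOSPHERIC, "uptake_amol_d"]
    h_in, h_atm = paired_histograms(u_in, u_atm, width=width)
    result = classify(h_in, h_atm)
    ha_count, ha_frac = highly_active_fraction(u_atm)
    (out / "histograms.json").write_text(
        json.dumps(
            {
                "bin_width": width,
                "anchor": h_in.anchor,
                "edges": h_in.edges.tolist(),
                "counts_insitu": h_in.counts.tolist(),
                "counts_atmospheric": h_atm.counts.tolist(),
            },
            indent=2,
        )
    )
    (out / "classification.json").write_text(
        json.dumps(
            {
                **result.to_dict(),
                "conversion_slope": conv.slope,
                "conversion_r2": conv.r2,
                "highly_active_count_atm": ha_count,
                "highly_active_fraction_atm": ha_frac,
                "geometry": geometry,
            },
            indent=2,
        )
    )
    done("classification")

    # --- taxon-level paired tests ----------------------------------------
    stage("taxon_tests")
    test_rows = []
    samples = sorted(cells["sample_id"].unique()) if "sample_id" in cells else []
    if len(samples) >= 3:
        means = (
            active.groupby(["taxon", "sample_id", "condition"])["uptake_amol_d"]
            .mean()
            .unstack("condition")
            .dropna()
        )
        for taxon, grp in means.groupby(level="taxon"):
            if len(grp) >= 3:
                res = taxon_paired_test(grp[IN_SITU], grp[ATMOSPHERIC], taxon=str(taxon))
                test_rows.append(
                    {
                        "taxon": taxon,
                        "test_used": res.test_used,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "n_pairs": res.n_pairs,
                        "degenerate": res.degenerate,
                    }
                )
    pd.DataFrame(
        test_rows, columns=["taxon", "test_used", "statistic", "p_value", "n_pairs", "degenerate"]
    ).to_csv(out / "taxon_tests.csv", index=False)
    done("taxon_tests")

    # --- carbon budget ----------------------------------------------------
    stage("budget")
    budget_inputs = pd.read_csv(ds / "budget_inputs.csv")
    budget = budget_table(budget_inputs, fit, cfs=cf, cap_at_100=cap_at_100)
    budget.to_csv(out / "budget.csv", index=False)
    done("budget")

    _report(out, fit, result, conv, ha_frac, budget, width, geometry)
    cfg_path = ds / "config.yaml"
    cfg = SyntheticConfig.from_yaml(cfg_path).seed if cfg_path.exists() else None
    _manifest(
        out,
        cfg,
        {"dataset": str(ds), "cf": list(cf), "geometry": geometry, "bin_width": width,
         "cap_at_100": cap_at_100},
        {k: v for k, v in stages.items() if isinstance(v, float)},
    )
    return out


def _report(out: Path, fit, result, conv, ha_frac, budget, width, geometry) -> None:
    bathy = budget[(budget["depth_m"] > 1000) & (budget["cf_kg_c_per_mol"] == 1.55)]
    lines = [
        "# Pressure-response analysis report",
        "",
        "## Depth power law (in-situ % of atmospheric)",
        f"- P(z) = {fit.a:.1f} · z^{fit.b:.3f}  (n={fit.n}, r²={fit.r2:.3f})",
        f"- 95% CI exponent: [{fit.ci_b[0]:.3f}, {fit.ci_b[1]:.3f}]",
        f"- 95% CI log10 coefficient: [{fit.ci_log10_a[0]:.3f}, {fit.ci_log10_a[1]:.3f}]",
        "",
        "## Single-cell conversion",
        f"- through-origin slope: {conv.slope:.3e} µm³ per pmol Leu (r²={conv.r2:.3f}, n={conv.n})",
        f"- geometry: {geometry}; histogram bin width {width} log10 units",
        "",
        "## Piezo classification (fractions of active cells)",
        f"- piezotolerant: {100*result.tolerant:.1f}%",
        f"- piezosensitive: {100*result.sensitive_min:.1f}–{100*result.sensitive_max:.1f}% "
        f"(midpoint {100*result.sensitive_mid:.1f}%)",
        f"- piezophilic: {100*result.philic_min:.1f}–{100*result.philic_max:.1f}% "
        f"(midpoint {100*result.philic_mid:.1f}%)",
        f"- highly active (>0.5 amol cell⁻¹ d⁻¹) under atmospheric pressure: {100*ha_frac:.1f}%",
        "",
        "## Carbon budget (CF 1.55 kg C mol⁻¹, in-situ corrected, bathypelagic)",
    ]
    for _, r in bathy.iterrows():
        lines.append(
            f"- {r['depth_m']:.0f} m: PCD {r['pcd_umol_m3_d']:.2f} µmol C m⁻³ d⁻¹, "
            f"POC_a {r['poc_a_mmol_m3_d']*1000:.2f} µmol C m⁻³ d⁻¹, "
            f"PCD:POC_a = {r['pcd_poc_ratio']:.2f}"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")


def classify_synthetic_community(config: SyntheticConfig, seed: int):
    """Generate one paired community and run the full single-cell chain.

    Returns ``(classification, conversion_fit, u_insitu, u_atm, truth)``
    where the uptakes are recovered through halo area → volume → conversion
    slope, exactly as ``cmd_analyze`` does on a dataset directory.
    """
    from .synthetic import gen_conversion_pairs, gen_paired_community

    cells, truth = gen_paired_community(config, seed)
    pairs = gen_conversion_pairs(config, rng=seed + 1000)
    conv = fit_conversion(
        list(zip(pairs["bulk_rate_pmol_l_h"], pairs["halo_volume_rate_um3_l_h"]))
    )
    u = np.array(
        [
            cell_uptake(halo_volume(a, config.geometry), d, conv)
            for a, d in zip(cells["halo_area_um2"], cells["duration_h"])
        ]
    )
    u_in = u[(cells["condition"] == IN_SITU).to_numpy()]
    u_atm = u[(cells["condition"] == ATMOSPHERIC).to_numpy()]
    h_in, h_atm = paired_histograms(u_in, u_atm)
    return classify(h_in, h_atm), conv, u_in, u_atm, truth


def cmd_recover(config: SyntheticConfig, outdir) -> dict:
    """Simulate-then-analyze loop comparing recovered values to truth.

    Tolerances: generator exponent inside the fit's 95% CI and recovered
    within ±15%; class-fraction midpoints within ±5 percentage points;
    conversion slope within ±5%.
    """
    out = Path(outdir)
    ds = cmd_simulate(config, out / "dataset")
    res_dir = cmd_analyze(ds, out / "results")
    fit = json.loads((res_dir / "fit.json").read_text())
    cls = json.loads((res_dir / "classification.json").read_text())

    checks = {}
    b_true = config.attenuation_exp
    checks["exponent_in_ci"] = bool(fit["ci95_b"][0] <= b_true <= fit["ci95_b"][1])
    checks["exponent_within_15pct"] = bool(abs(fit["b_exponent"] - b_true) <= 0.15 * abs(b_true))
    f_tol, f_sen, f_phi = config.class_fractions
    checks["tolerant_within_5pts"] = bool(abs(cls["tolerant"] - f_tol) <= 0.05)
    checks["sensitive_within_5pts"] = bool(abs(cls["sensitive_mid"] - f_sen) <= 0.05)
    checks["philic_within_5pts"] = bool(abs(cls["philic_mid"] - f_phi) <= 0.05)
    checks["slope_within_5pct"] = bool(
        abs(cls["conversion_slope"] - config.conversion_slope) <= 0.05 * config.conversion_slope
    )
    report = {
        "recovered": {
            "a": fit["a_percent_at_1m"],
            "b": fit["b_exponent"],
            "tolerant": cls["tolerant"],
            "sensitive_mid": cls["sensitive_mid"],
            "philic_mid": cls["philic_mid"],
            "conversion_slope": cls["conversion_slope"],
        },
        "truth": {
            "a": config.attenuation_coeff,
            "b": b_true,
            "tolerant": f_tol,
            "sensitive": f_sen,
            "philic": f_phi,
            "conversion_slope": config.conversion_slope,
        },
        "checks": checks,
        "all_pass": all(checks.values()),
    }
    (out / "recovery.json").write_text(json.dumps(report, indent=2))
    return report
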
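"""Sweep tables, figure-style summaries, and the command-line interface.

Each sub-report regenerates one of the package's standard experiments as a
machine-readable table:

* ``forms``  -- (f, K) sweep of the cost-benefit form: optima and selection
  against gene loss / halving / 1% reduction, plus the correlation of the
  halving cost with P_opt vs with net benefit.
* ``mm``     -- flux and perturbation curves of the two-step reversible
  Michaelis-Menten pathway across Km and dilution-cost settings.
* ``growth`` -- per-setting optima and perturbation costs of the 20-amino-
  acid growth model over seeded random parameter draws.
* ``mca``    -- the closed-form metabolic-control selection coefficients.
* ``evolution`` -- the population-genetic worked arithmetic.
* ``paper-report`` -- all quantitative headline numbers in one JSON.

Every output embeds a provenance header (seed, config hash, package
version); identical config + seed give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from exprsel import __version__
from exprsel.core_forms import (
    CostBenefitParams,
    net_benefit,
    optimum_cost_benefit,
    selection_exact,
    selection_quadratic,
)
from exprsel.growth_model import (
    GrowthParams,
    half_max_expression,
    optimize_allocation,
    perturb_focal,
    steady_state_growth,
)
from exprsel.mca import selection_mca
from exprsel.mm_pathway import (
    MMPathwayParams,
    dilution_coefficient,
    optimize_expression,
    perturbation_cost,
)
from exprsel.evolution import worked_arithmetic
from exprsel.synthetic_params import GridSpec, fk_grid, sample_growth_params

logger = logging.getLogger("exprsel")

STANDARD_FACTORS = (0.0, 0.5, 0.99, 1.01, 2.0)


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance(seed: int | None, config: dict | None = None) -> dict:
    return {
        "seed": seed,
        "config_hash": _config_hash(config or {}),
        "package_version": __version__,
    }


def write_table(df: pd.DataFrame, path: Path, header: dict, fmt: str = "csv") -> None:
    """Write a sweep table with a provenance header (CSV comments or JSON field)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for key, value in header.items():
                fh.write(f"# {key}: {value}\n")
            df.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {"provenance": header, "rows": df.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1, default=float) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# cost-benefit (f, K) sweep


def run_fig2_sweep(grid: GridSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Sweep the cost-benefit form over the retained (f, K) grid.

    For each point: the optimum, net benefit at the optimum, and the
    selection against expression factors 0 (gene loss), 0.5 and 0.99.
    The summary correlates log10 s(halving) with log10 P_opt and with
    log10 net benefit (both quantities span orders of magnitude, so the
    correlation is computed on log scale): selection against a 2-fold
    reduction tracks the expression level, not the gene's importance.
    """
    points = fk_grid(grid)
    rows = []
    for p in points:
        P_opt, s_opt = optimum_cost_benefit(p)
        row = {"f": p.f, "K": p.K, "P_opt": P_opt, "net_benefit": net_benefit(P_opt, p)}
        for factor in (0.0, 0.5, 0.99):
            row[f"s_factor_{factor}"] = selection_exact(p, factor).s
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) < 2:
        raise ValueError("correlations undefined for fewer than two grid points")
    logs = np.log10(df["s_factor_0.5"])
    summary = {
        "n_points": len(df),
        "r_log_s_halving_vs_log_P_opt": float(np.corrcoef(logs, np.log10(df["P_opt"]))[0, 1]),
        "r_log_s_halving_vs_log_net_benefit": float(
            np.corrcoef(logs, np.log10(df["net_benefit"]))[0, 1]
        ),
    }
    return df, summary


# ---------------------------------------------------------------------------
# Michaelis-Menten pathway curves


def run_fig3(
    Km_values: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
    mw_ratios: tuple[float | None, ...] = (None, 100.0, 10.0),
    factors: tuple[float, ...] = STANDARD_FACTORS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flux curves and perturbation costs for the two-step pathway.

    ``mw_ratios`` selects the dilution-cost settings: None for no cost,
    otherwise the intermediate's weight is 1/mw_ratio of an enzyme's.

    Returns (curves, perturbations); curve rows hold (Km, cost, P, I, flux,
    net_flux), perturbation rows hold x = P/P_opt and y = s/P_opt.
    """
    curve_rows, pert_rows = [], []
    for mw in mw_ratios:
        c = 0.0 if mw is None else dilution_coefficient(mw)
        for Km in Km_values:
            params = MMPathwayParams(Km=Km, dilution_cost=c)
            best, curve = optimize_expression(params)
            for st in curve:
                curve_rows.append(
                    {"Km": Km, "dilution_cost": c, "P": st.P, "I": st.I,
                     "flux": st.flux, "net_flux": st.net_flux}
                )
            for factor in factors:
                if factor == 0.0:
                    continue  # zero expression carries no flux; skip in curves
                y = perturbation_cost(params, best, factor)
                pert_rows.append(
                    {"Km": Km, "dilution_cost": c, "P_opt": best.P,
                     "I_opt": best.I, "factor": factor, "s": y * best.P,
                     "s_over_P_opt": y}
                )
    return pd.DataFrame(curve_rows), pd.DataFrame(pert_rows)


# ---------------------------------------------------------------------------
# growth model point cloud


def run_fig4(
    n: int = 100,
    seed: int = 0,
    factors: tuple[float, ...] = (0.5, 0.99, 1.01, 2.0),
) -> tuple[pd.DataFrame, dict]:
    """Optimize the growth model for ``n`` seeded random parameter settings.

    Per setting: the optimal allocation, the fitness cost of each
    perturbation factor, and the half-max expression level.  The summary
    reports medians and ranges.  Any optimizer failure is counted and the
    offending setting excluded; ``n_failed`` must be 0 for a clean run.
    """
    draws = sample_growth_params(n, seed)
    rows = []
    n_failed = 0
    for i, draw in enumerate(draws):
        params = GrowthParams(f=draw.f, r=draw.r)
        try:
            alloc, g_opt = optimize_allocation(params)
            row = {
                "setting": i, "f1": draw.f1, "r1": draw.r1,
                "R_opt": alloc.R, "E1_opt": float(alloc.E[0]), "g_opt": g_opt,
            }
            for factor in factors:
                s = perturb_focal(params, alloc, factor, g_opt=g_opt)
                row[f"s_factor_{factor}"] = s
                row[f"s_over_P_opt_factor_{factor}"] = s / row["E1_opt"]
            K_half, ratio = half_max_expression(params, alloc, g_opt=g_opt)
            row["K_half"] = K_half
            row["P_opt_over_K_half"] = ratio
            rows.append(row)
        except RuntimeError as exc:  # pragma: no cover - should not happen
            n_failed += 1
            logger.warning("setting %d failed: %s", i, exc)
    df = pd.DataFrame(rows)
    summary = {
        "n_settings": n,
        "n_failed": n_failed,
        "f1_median": float(df["f1"].median()),
        "f1_range": [float(df["f1"].min()), float(df["f1"].max())],
        "E1_opt_median": float(df["E1_opt"].median()),
        "E1_opt_range": [float(df["E1_opt"].min()), float(df["E1_opt"].max())],
        "s_halving_median": float(df["s_factor_0.5"].median()),
        "s_halving_range": [float(df["s_factor_0.5"].min()), float(df["s_factor_0.5"].max())],
        "s_doubling_over_P_opt_range": [
            float(df["s_over_P_opt_factor_2.0"].min()),
            float(df["s_over_P_opt_factor_2.0"].max()),
        ],
        "P_opt_over_K_half_median": float(df["P_opt_over_K_half"].median()),
    }
    return df, summary


# ---------------------------------------------------------------------------
# headline numbers


def paper_numbers(seed: int = 0, n_growth: int = 100) -> dict:
    """Recompute every headline quantity of the analysis from scratch."""
    cb = CostBenefitParams(f=1.0, K=1e-6)
    halving = selection_exact(cb, 0.5)
    P_opt_essential, _ = optimum_cost_benefit(CostBenefitParams(f=1.0, K=2e-7))

    params0 = MMPathwayParams(Km=1.0)
    best0, _ = optimize_expression(params0)
    params_c = MMPathwayParams(Km=1.0, dilution_cost=dilution_coefficient(100.0))
    best_c, _ = optimize_expression(params_c)

    _, growth = run_fig4(n=n_growth, seed=seed)

    return {
        "cost_benefit_s_halving_over_P_opt": halving.s_over_P_opt,
        "cost_benefit_s_1pct_over_P_opt": selection_quadratic(0.01, 1.0),
        "P_opt_essential_min_K": P_opt_essential,
        "mca_s_doubling_over_P_opt": selection_mca(1.0, 1.0),
        "mca_s_halving_over_P_opt": selection_mca(-0.5, 1.0),
        "mca_s_1pct_over_P_opt": selection_mca(0.01, 1.0),
        "mm_P_opt_pct": 100.0 * best0.P,
        "mm_I_opt_mM": best0.I,
        "mm_P_opt_with_cost_pct": 100.0 * best_c.P,
        "mm_I_opt_with_cost_mM": best_c.I,
        "mm_s_doubling_over_P_opt": perturbation_cost(params0, best0, 2.0),
        "mm_s_halving_over_P_opt": perturbation_cost(params0, best0, 0.5),
        "growth_model": growth,
        "evolution": worked_arithmetic(),
    }


# ---------------------------------------------------------------------------
# CLI


def _load_config(path: str | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise click.BadParameter("config must be a flat key-value YAML mapping")
    return config


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log at DEBUG level.")
def main(verbose: bool) -> None:
    """Regenerate the package's model sweeps as CSV/JSON tables."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


_common = [
    click.option("--seed", type=int, default=0, show_default=True),
    click.option("--config", "config_path", type=click.Path(exists=True), default=None),
    click.option("--out", "out_dir", type=click.Path(), default="out", show_default=True),
    click.option("--format", "fmt", type=click.Choice(["csv", "json"]), default="csv",
                 show_default=True),
]


def common_options(fn):
    for opt in reversed(_common):
        fn = opt(fn)
    return fn


@main.command()
@common_options
def forms(seed: int, config_path: str | None, out_dir: str, fmt: str) -> None:
    """Cost-benefit (f, K) sweep with selection correlations."""
    config = _load_config(config_path)
    spec = GridSpec(**config.get("grid", {}))
    df, summary = run_fig2_sweep(spec)
    header = provenance(seed, config)
    out = Path(out_dir)
    write_table(df, out / f"forms_sweep.{fmt}", header, fmt)
    (out / "forms_summary.json").write_text(
        json.dumps({"provenance": header, **summary}, indent=1) + "\n")
    click.echo(json.dumps(summary, indent=1))


@main.command()
@common_options
def mm(seed: int, config_path: str | None, out_dir: str, fmt: str) -> None:
    """Two-step Michaelis-Menten pathway curves and perturbations."""
    config = _load_config(config_path)
    curves, perts = run_fig3(**config.get("mm", {}))
    header = provenance(seed, config)
    out = Path(out_dir)
    write_table(curves, out / f"mm_curves.{fmt}", header, fmt)
    write_table(perts, out / f"mm_perturbations.{fmt}", header, fmt)
    click.echo(f"wrote {len(curves)} curve rows, {len(perts)} perturbation rows")


@main.command()
@common_options
@click.option("--n", type=int, default=100, show_default=True,
              help="Number of random parameter settings.")
def growth(seed: int, config_path: str | None, out_dir: str, fmt: str, n: int) -> None:
    """Growth-model optimization over seeded random parameter settings."""
    config = _load_config(config_path)
    df, summary = run_fig4(n=n, seed=seed)
    header = provenance(seed, config)
    out = Path(out_dir)
    write_table(df, out / f"growth_settings.{fmt}", header, fmt)
    (out / "growth_summary.json").write_text(
        json.dumps({"provenance": header, **summary}, indent=1) + "\n")
    click.echo(json.dumps(summary, indent=1))


@main.command()
@common_options
def mca(seed: int, config_path: str | None, out_dir: str, fmt: str) -> None:
    """Closed-form metabolic control analysis selection coefficients."""
    config = _load_config(config_path)
    rows = [
        {"epsilon": eps, "s_over_P_opt": selection_mca(eps, 1.0)}
        for eps in (-0.5, -0.01, 0.01, 1.0)
    ]
    df = pd.DataFrame(rows)
    write_table(df, Path(out_dir) / f"mca.{fmt}", provenance(seed, config), fmt)
    click.echo(df.to_string(index=False))


@main.command()
@common_options
def evolution(seed: int, config_path: str | None, out_dir: str, fmt: str) -> None:
    """Population-genetic worked arithmetic as a small JSON report."""
    config = _load_config(config_path)
    report = {"provenance": provenance(seed, config), **worked_arithmetic()}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "evolution.json").write_text(json.dumps(report, indent=1) + "\n")
    click.echo(json.dumps(report, indent=1))


@main.command(name="paper-report")
@common_options
@click.option("--n", type=int, default=100, show_default=True)
def paper_report(seed: int, config_path: str | None, out_dir: str, fmt: str, n: int) -> None:
    """All headline numbers of the analysis in one JSON file."""
    config = _load_config(config_path)
    report = {"provenance": provenance(seed, config),
              **paper_numbers(seed=seed, n_growth=n)}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "paper_report.json").write_text(json.dumps(report, indent=1) + "\n")
    click.echo(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
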
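"""Two-step reversible Michaelis-Menten pathway S <-> I <-> E.

A substrate S (fixed boundary concentration) is converted via an intermediate
I to an end product E (also fixed).  Enzyme 1 carries a fraction ``P`` of
total protein with specific activity ``activity_ratio`` per unit mass;
enzyme 2 carries the rest (``V2 = 1 - P``).  For each P the intermediate
concentration is solved so the two step fluxes balance; optionally the flux
is divided by ``1 + I * c`` to charge a dilution cost for accumulating
intermediates.

The steady-state residual flux1(I) - flux2(I) is strictly decreasing in I on
the thermodynamically allowed bracket (E/Keq2, S*Keq1), so Brent's method
converges to the unique root.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "MMPathwayParams",
    "MMSteadyState",
    "reversible_mm_rate",
    "steady_state",
    "optimize_expression",
    "perturbation_cost",
    "dilution_coefficient",
]

#: total concentration of protein monomers in the cell, mM (BioNumbers 104726)
TOTAL_PROTEIN_MM = 4.0

#: default expression grid: P = 5e-4 to 0.5 stepping by 5e-4
GRID_START = 5e-4
GRID_STOP = 0.5
GRID_STEP = 5e-4


def dilution_coefficient(mw_ratio: float, total_protein_mM: float = TOTAL_PROTEIN_MM) -> float:
    """Per-mM flux-dilution coefficient for intermediates.

    An intermediate ``mw_ratio``-fold lighter than an enzyme dilutes the
    4 mM pool of protein monomers by ``I / (mw_ratio * total_protein)`` per
    mM of intermediate, so ``c = 1 / (mw_ratio * total_protein_mM)``.
    ``mw_ratio = 100`` is the standard case, ``10`` the expensive-intermediate
    variant.
    """
    if mw_ratio <= 0 or total_protein_mM <= 0:
        raise ValueError("mw_ratio and total protein concentration must be positive")
    return 1.0 / (mw_ratio * total_protein_mM)


@dataclass(frozen=True)
class MMPathwayParams:
    """Kinetic constants and boundary concentrations for the two-step pathway.

    Parameters
    ----------
    S : float
        Substrate concentration, mM.
    E_end : float
        End-product concentration, mM.
    Keq1, Keq2 : float
        Equilibrium constants of the two steps (both mildly favorable at 10).
    Km : float
        Shared Michaelis constant for every forward/reverse saturation term, mM.
    activity_ratio : float
        Activity of enzyme 1 per unit mass relative to enzyme 2
        (``V1 = activity_ratio * P``; ``V2 = 1 - P``).
    dilution_cost : float
        Per-mM coefficient c; realized flux is divided by ``1 + I * c``.
    focal_step : int
        Which enzyme the expression fraction P refers to (1 or 2).  The
        focal enzyme always carries the high specific activity (so that its
        optimal expression stays moderate): with ``focal_step = 2``,
        ``V2 = activity_ratio * P`` and ``V1 = 1 - P``.
    """

    S: float = 2.0
    E_end: float = 1.0
    Keq1: float = 10.0
    Keq2: float = 10.0
    Km: float = 1.0
    activity_ratio: float = 100.0
    dilution_cost: float = 0.0
    focal_step: int = 1

    def __post_init__(self) -> None:
        for name in ("S", "E_end", "Keq1", "Keq2", "Km", "activity_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.dilution_cost < 0:
            raise ValueError(f"dilution_cost must be >= 0, got {self.dilution_cost}")
        if self.focal_step not in (1, 2):
            raise ValueError(f"focal_step must be 1 or 2, got {self.focal_step}")
        # intermediate bracket must be non-empty: E/Keq2 < S*Keq1
        if self.E_end / self.Keq2 >= self.S * self.Keq1:
            raise ValueError("thermodynamically infeasible: E_end/Keq2 >= S*Keq1")


@dataclass(frozen=True)
class MMSteadyState:
    """Steady state of the pathway at one expression fraction.

    ``net_flux = flux / (1 + I * c)``; with zero dilution cost the two
    coincide.  Because the dilution factor divides both step fluxes equally,
    the same intermediate concentration solves the costed and costless
    systems.
    """

    P: float
    I: float
    flux: float
    net_flux: float


def reversible_mm_rate(
    substrate: float, product: float, Keq: float, Kf: float, Kr: float, V: float
) -> float:
    """Reversible Michaelis-Menten rate.

    ``(substrate - product/Keq) * (V/Kf) / (1 + substrate/Kf + product/Kr)``:
    a thermodynamic driving term times activity, damped by saturation with
    both reactant pools.  Linear in V; exactly zero at equilibrium
    (product = substrate * Keq).
    """
    if Keq <= 0 or Kf <= 0 or Kr <= 0:
        raise ValueError("Keq, Kf and Kr must be positive")
    return (substrate - product / Keq) * (V / Kf) / (1.0 + substrate / Kf + product / Kr)


def _activities(params: MMPathwayParams, P: float) -> tuple[float, float]:
    if params.focal_step == 1:
        return params.activity_ratio * P, 1.0 - P
    return 1.0 - P, params.activity_ratio * P


def steady_state(params: MMPathwayParams, P: float) -> MMSteadyState:
    """Solve for the intermediate concentration balancing the two step fluxes.

    Brackets I in the open interval (E_end/Keq2, S*Keq1), outside which one
    of the steps runs backwards; the residual is strictly monotone there.
    """
    if not (0.0 < P < 1.0):
        raise ValueError(f"expression fraction P must be in (0, 1), got {P}")
    V1, V2 = _activities(params, P)
    Km = params.Km

    def residual(I: float) -> float:
        f1 = reversible_mm_rate(params.S, I, params.Keq1, Km, Km, V1)
        f2 = reversible_mm_rate(I, params.E_end, params.Keq2, Km, Km, V2)
        return f1 - f2

    lo = params.E_end / params.Keq2
    hi = params.S * params.Keq1
    eps = 1e-13
    a, b = lo * (1 + eps) + 1e-300, hi * (1 - eps)
    if residual(a) <= 0 or residual(b) >= 0:
        raise RuntimeError(
            f"steady-state bracket failed for P={P}: no sign change on ({lo}, {hi})"
        )
    I = brentq(residual, a, b, xtol=1e-12, rtol=8.9e-16)
    flux = reversible_mm_rate(params.S, I, params.Keq1, Km, Km, V1)
    net = flux / (1.0 + I * params.dilution_cost)
    return MMSteadyState(P=P, I=I, flux=flux, net_flux=net)


def expression_grid(
    start: float = GRID_START, stop: float = GRID_STOP, step: float = GRID_STEP
) -> np.ndarray:
    """The P grid used for optimization (inclusive of both ends)."""
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    if grid[0] <= 0 or grid[-1] >= 1:
        raise ValueError("expression grid must lie within (0, 1)")
    return grid


def optimize_expression(
    params: MMPathwayParams,
    grid: np.ndarray | None = None,
    refine: bool = False,
) -> tuple[MMSteadyState, list[MMSteadyState]]:
    """Grid-maximize the (dilution-corrected) flux over the expression fraction.

    Returns the optimum state and the full flux curve.  With ``refine=True``
    the grid argmax is polished by bounded scalar minimization between its
    neighbors; the refined optimum matters only for sub-percent perturbations,
    where the 5e-4 grid resolution would otherwise dominate the signal.
    """
    if grid is None:
        grid = expression_grid()
    curve = [steady_state(params, float(P)) for P in grid]
    i = int(np.argmax([st.net_flux for st in curve]))
    best = curve[i]
    if refine:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda P: -steady_state(params, P).net_flux,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = steady_state(params, float(res.x))
    return best, curve


def perturbation_cost(
    params: MMPathwayParams, optimum: MMSteadyState, factor: float
) -> float:
    """Relative flux loss, per unit P_opt, of scaling expression by ``factor``.

    Re-solves the steady state at ``factor * P_opt`` (the other enzyme's
    activity is recomputed from its ``1 - P`` share) and returns
    ``s / P_opt`` with ``s = 1 - net_flux(factor * P_opt) / net_flux(P_opt)``.
    """
    P = factor * optimum.P
    if not (0.0 < P < 1.0):
        raise ValueError(f"perturbed expression {P} outside (0, 1)")
    perturbed = steady_state(params, P)
    s = 1.0 - perturbed.net_flux / optimum.net_flux
    return s / optimum.P
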
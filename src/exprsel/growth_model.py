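"""Coarse-grained growth model: 20 amino acids assembled by a "ribosome".

The proteome is split between a ribosome fraction R and 20 enzyme fractions
E_i, one per amino acid, with R + sum(E_i) = 1.  Each enzyme synthesizes its
amino acid with unsaturated reversible kinetics (substrate 1, equilibrium
constant 10): production_i = E_i * r_i * (1 - A_i / 10).  The ribosome
incorporates amino acids as first-order steps, so protein synthesis -- and
hence growth -- runs at

    g = R / sum_i(f_i / A_i)

the ribosome concentration times the f-weighted harmonic mean of the amino
acid concentrations.  At steady state consumption matches production for
every amino acid: g * f_i = E_i * r_i * (1 - A_i / 10).

Substituting A_i(g) = 10 * (1 - g * f_i / (E_i * r_i)) into the growth-rate
expression reduces the 20-dimensional balance system to a single fixed-point
equation in g, solved by bracketed root-finding on (0, min_i E_i*r_i/f_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize

__all__ = [
    "GrowthParams",
    "Allocation",
    "GrowthSteadyState",
    "InfeasibleAllocationError",
    "growth_rate",
    "steady_state_growth",
    "optimize_allocation",
    "perturb_focal",
    "half_max_expression",
]

#: amino-acid precursor concentration (fixed)
SUBSTRATE = 1.0
#: equilibrium constant of amino-acid synthesis; A_i saturates below S*Keq = 10
KEQ = 10.0
N_AA = 20


class InfeasibleAllocationError(ValueError):
    """Raised when an allocation admits no steady state with all A_i > 0."""


@dataclass(frozen=True)
class GrowthParams:
    """Amino-acid usage fractions and enzyme rate constants.

    ``f`` sums to 1; ``r`` has mean 5 (enzymes on average 5-fold faster per
    unit mass than the ribosome, whose rate is fixed at 1).  Only the focal
    amino acid (index 0) has distinct values; the other 19 are equal.
    """

    f: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "r", r)
        if f.shape != (N_AA,) or r.shape != (N_AA,):
            raise ValueError(f"f and r must have shape ({N_AA},)")
        if np.any(f <= 0) or np.any(r <= 0):
            raise ValueError("usage fractions and rates must be positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"usage fractions must sum to 1, got {f.sum()}")
        if abs(r.mean() - 5.0) > 1e-9:
            raise ValueError(f"enzyme rates must have mean 5, got {r.mean()}")


@dataclass(frozen=True)
class Allocation:
    """Proteome split: ribosome fraction R and 20 enzyme fractions E."""

    R: float
    E: np.ndarray

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        if E.shape != (N_AA,):
            raise ValueError(f"E must have shape ({N_AA},)")
        if self.R <= 0 or np.any(E <= 0):
            raise ValueError("all proteome fractions must be positive")
        total = self.R + E.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proteome fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class GrowthSteadyState:
    """Steady-state amino-acid concentrations and growth rate."""

    A: np.ndarray
    g: float


def growth_rate(R: float, A: np.ndarray, f: np.ndarray) -> float:
    """Protein synthesis rate ``g = R / sum(f_i / A_i)``."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("amino-acid concentrations must be positive")
    return R / float(np.sum(np.asarray(f, dtype=float) / A))


def _solve_g(f: np.ndarray, r: np.ndarray, R: float, E: np.ndarray) -> float:
    """Scalar fixed point for g; raises InfeasibleAllocationError if none."""
    capacity = E * r / f  # g may not exceed any enzyme's supply ceiling
    g_upper = float(capacity.min())
    if g_upper <= 0:
        raise InfeasibleAllocationError("an enzyme has zero synthesis capacity")

    def phi(g: float) -> float:
        A = 10.0 * (1.0 - g / capacity)
        return R / np.sum(f / A) - g

    hi = g_upper * (1.0 - 1e-13)
    # phi(0+) = 10*R / sum(f) > 0; phi(g_upper-) < 0 since some A_i -> 0
    if phi(hi) >= 0:
        raise InfeasibleAllocationError("no steady state below the capacity bound")
    return brentq(phi, 0.0, hi, xtol=1e-15, rtol=8.9e-16)


def steady_state_growth(params: GrowthParams, alloc: Allocation) -> GrowthSteadyState:
    """Solve the amino-acid balance ``g * f_i = E_i * r_i * (1 - A_i / 10)``.

    Uses the 1-D reduction in g (see module docstring) rather than a
    20-dimensional least-squares search; the fixed point is identical and
    bracketing makes convergence unconditional.
    """
    g = _solve_g(params.f, params.r, alloc.R, alloc.E)
    A = 10.0 * (1.0 - g * params.f / (alloc.E * params.r))
    return GrowthSteadyState(A=A, g=g)


def _symmetric_alloc(R: float, E1: float) -> Allocation:
    E = np.full(N_AA, (1.0 - R - E1) / (N_AA - 1))
    E[0] = E1
    return Allocation(R=R, E=E)


_STARTS = ((0.4, 0.03), (0.3, 0.10), (0.5, 0.01), (0.2, 0.05))


def optimize_allocation(params: GrowthParams) -> tuple[Allocation, float]:
    """Maximize the growth rate over (R, E1) with the other 19 enzymes equal.

    Because amino acids 2..20 share their parameters, the optimum has
    E_2 = ... = E_20 = (1 - R - E1) / 19, leaving a 2-D problem solved by
    Nelder-Mead from four starting points (infeasible trial points are
    penalized).  For fully symmetric parameters (f_i = 1/20, r_i = 5) the
    optimum is known in closed form: R = sqrt(2) - 1, g = 10*R*(1-R)/(1+R).
    """
    f, r = params.f, params.r

    def neg_g(x: np.ndarray) -> float:
        R, E1 = x
        if R <= 1e-9 or E1 <= 1e-9 or R + E1 >= 1.0 - 1e-9:
            return 1e6
        E = np.full(N_AA, (1.0 - R - E1) / (N_AA - 1))
        E[0] = E1
        try:
            return -_solve_g(f, r, R, E)
        except InfeasibleAllocationError:
            return 1e6

    best = None
    for x0 in _STARTS:
        res = minimize(
            neg_g,
            np.asarray(x0),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e6:
        raise RuntimeError("allocation optimizer failed to find a feasible optimum")
    R, E1 = best.x
    return _symmetric_alloc(float(R), float(E1)), -float(best.fun)


def _rescaled_alloc(alloc: Allocation, factor: float) -> Allocation:
    """Scale the focal enzyme by ``factor``; rescale everything else to sum 1."""
    E1 = alloc.E[0]
    E1p = factor * E1
    if E1p <= 0 or E1p >= 1.0:
        raise ValueError(f"perturbed focal expression {E1p} outside (0, 1)")
    scale = (1.0 - E1p) / (1.0 - E1)
    E = alloc.E * scale
    E[0] = E1p
    return Allocation(R=alloc.R * scale, E=E)


def perturb_focal(
    params: GrowthParams, alloc_opt: Allocation, factor: float, g_opt: float | None = None
) -> float:
    """Fitness cost ``s = 1 - g_perturbed / g_opt`` of scaling the focal enzyme.

    All other proteins -- ribosome included -- are rescaled by a common
    factor ``(1 - factor*E1) / (1 - E1)`` so total protein stays 1, the
    compensation a promoter mutation in one gene would impose on the rest
    of the proteome.
    """
    if g_opt is None:
        g_opt = steady_state_growth(params, alloc_opt).g
    g_pert = steady_state_growth(params, _rescaled_alloc(alloc_opt, factor)).g
    return 1.0 - g_pert / g_opt


def half_max_expression(
    params: GrowthParams, alloc_opt: Allocation, g_opt: float | None = None
) -> tuple[float, float]:
    """Expression level below the optimum giving half the optimal growth rate.

    The analogue of the half-max investment K of the cost-benefit form:
    root-find on the scaling factor of the focal enzyme (downward branch,
    where g is increasing in expression) for g = g_opt / 2.

    Returns
    -------
    (K_half, ratio) : the half-max expression level and P_opt / K_half.
    """
    if g_opt is None:
        g_opt = steady_state_growth(params, alloc_opt).g
    E1 = alloc_opt.E[0]

    def excess(factor: float) -> float:
        return steady_state_growth(params, _rescaled_alloc(alloc_opt, factor)).g - g_opt / 2.0

    lo = 1e-9
    if excess(lo) >= 0:
        raise RuntimeError(
            "growth never falls to half-max before the focal enzyme vanishes"
        )
    factor_half = brentq(excess, lo, 1.0, xtol=1e-14, rtol=8.9e-16)
    K_half = factor_half * E1
    return K_half, E1 / K_half
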
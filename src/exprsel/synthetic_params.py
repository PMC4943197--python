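"""Random parameter settings for the growth model and (f, K) grids.

The growth-model parameter draw mirrors a simple heavy-tailed recipe: the
focal amino acid's usage fraction is ``f1 = 2**N1 / sum_i 2**N_i`` with
N_i twenty standard normal variables (log2-normal share of a log2-normal
pool), the other 19 usages equal.  Enzyme rates follow the same share
distribution, independently drawn, rescaled so the 20 rates average 5.
Across many draws f1 has median ~0.043 and spans roughly 0.01-0.4.

``fk_grid`` builds the log-spaced (f, K) sweep for the cost-benefit form,
keeping only combinations that are net-beneficial (K < f) and whose optimal
expression falls in the realistic range observed for fitness-relevant
microbial proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from exprsel.core_forms import CostBenefitParams, optimum_cost_benefit

__all__ = ["ParameterDraw", "GridSpec", "sample_growth_params", "fk_grid"]

N_AA = 20
RATE_MEAN = 5.0


@dataclass(frozen=True)
class ParameterDraw:
    """One growth-model parameter setting (usage fractions and rates)."""

    f: np.ndarray
    r: np.ndarray

    @property
    def f1(self) -> float:
        return float(self.f[0])

    @property
    def r1(self) -> float:
        return float(self.r[0])


def _focal_share(rng: np.random.Generator) -> float:
    N = rng.standard_normal(N_AA)
    w = np.exp2(N)
    return float(w[0] / w.sum())


def sample_growth_params(n: int, seed: int) -> list[ParameterDraw]:
    """Draw ``n`` growth-model parameter settings, deterministically per seed.

    For each setting: ``f1 = 2**N1 / sum 2**N_i`` over 20 standard normals,
    ``f_i = (1 - f1) / 19`` for the rest; rates use an independent normal
    vector, ``r1 = 20 * RATE_MEAN * share``, the rest equal, so that
    ``mean(r) = 5`` exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        f1 = _focal_share(rng)
        r1 = N_AA * RATE_MEAN * _focal_share(rng)
        f = np.full(N_AA, (1.0 - f1) / (N_AA - 1))
        f[0] = f1
        r = np.full(N_AA, (N_AA * RATE_MEAN - r1) / (N_AA - 1))
        r[0] = r1
        draws.append(ParameterDraw(f=f, r=r))
    return draws


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced (f, K) grid with a filter on the optimal expression level.

    Defaults: f from 1e-5 (the weakest benefit that selection can maintain)
    to 1 (essential), K from 2e-7 (one protein copy per cell) to 0.1, ten
    points per decade, retaining combinations with P_opt in [5e-6, 0.03] --
    the expression range covering >95% of fitness-relevant proteins in
    E. coli and budding yeast.
    """

    f_range: tuple[float, float] = (1e-5, 1.0)
    K_range: tuple[float, float] = (2e-7, 1e-1)
    points_per_decade: int = 10
    P_opt_filter: tuple[float, float] = (5e-6, 0.03)

    def __post_init__(self) -> None:
        for lo, hi in (self.f_range, self.K_range, self.P_opt_filter):
            if not (0 <= lo < hi):
                raise ValueError("grid bounds must satisfy 0 <= lo < hi")
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")

    def axis(self, lo: float, hi: float) -> np.ndarray:
        n = int(round(np.log10(hi / lo) * self.points_per_decade)) + 1
        return np.logspace(np.log10(lo), np.log10(hi), n)


def fk_grid(spec: GridSpec | None = None) -> list[CostBenefitParams]:
    """Enumerate retained (f, K) combinations of the sweep grid.

    A point survives if the protein is net beneficial (K < f) and its
    optimal expression level lies inside ``spec.P_opt_filter``.  Raises if
    the filter excludes every point, which would silently break downstream
    sweeps.
    """
    if spec is None:
        spec = GridSpec()
    lo, hi = spec.P_opt_filter
    out: list[CostBenefitParams] = []
    for f in spec.axis(*spec.f_range):
        f = min(float(f), 1.0)  # guard against logspace endpoint rounding
        for K in spec.axis(*spec.K_range):
            K = float(K)
            if K >= f:
                continue
            params = CostBenefitParams(f=f, K=K)
            P_opt, _ = optimum_cost_benefit(params)
            if lo <= P_opt <= hi:
                out.append(params)
    if not out:
        raise ValueError("(f, K) grid filter retained no points")
    return out
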
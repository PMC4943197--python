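"""Closed-form cost-benefit and linear-pathway fitness forms.

Two closely related descriptions of how steady-state flux (taken as fitness)
depends on one protein's share ``P`` of total cellular protein:

* the **cost-benefit form** ``f * P / (K + P) - P`` -- a saturating benefit
  with maximum ``f``, half-saturating at ``K``, minus a linear cost equal to
  the expression level itself;
* the **metabolic form** ``P / (K + P / (1 - P))`` -- the exact flux of an
  unsaturated reversible two-enzyme pathway when the non-focal enzymes are
  rescaled by ``1 - P`` to keep total protein constant.

Both are maximized at ``P`` of order ``sqrt(K)`` and agree to within a couple
of percent for ``K <= 0.01``, which covers essentially all natural proteins.
Selection coefficients here are magnitudes: ``s >= 0`` always denotes a
fitness *reduction*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CostBenefitParams",
    "PerturbationResult",
    "net_benefit",
    "optimum_cost_benefit",
    "metabolic_form",
    "metabolic_optimum",
    "compare_forms",
    "selection_exact",
    "selection_quadratic",
    "reference_costs",
]

#: one protein copy per cell, as a fraction of total protein, for a small
#: bacterium -- the physical floor for the half-max investment K
MIN_K_REAL_PROTEIN = 2e-7


@dataclass(frozen=True)
class CostBenefitParams:
    """Parameters of the saturating cost-benefit form.

    Parameters
    ----------
    f : float
        Maximum possible benefit of the protein, as a fraction of fitness,
        in (0, 1].  ``f = 1`` for an essential protein.
    K : float
        Expression fraction at which the benefit reaches ``f / 2``;
        also the cost incurred at half-max benefit.  Must satisfy
        ``0 < K < f`` for the protein to be net beneficial at any level.
    """

    f: float
    K: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f <= 1.0):
            raise ValueError(f"maximum benefit f must be in (0, 1], got {self.f}")
        if not (0.0 < self.K < 1.0):
            raise ValueError(f"half-max investment K must be in (0, 1), got {self.K}")
        if self.K >= self.f:
            raise ValueError(
                f"K >= f ({self.K} >= {self.f}): no expression level is net beneficial"
            )


@dataclass(frozen=True)
class PerturbationResult:
    """Outcome of perturbing expression away from its optimum.

    Attributes
    ----------
    P_opt : float
        Optimal expression fraction.
    factor : float
        Multiplicative change ``x = P / P_opt``; 0 means gene loss.
    epsilon : float
        Relative change ``factor - 1``.
    s : float
        Selection coefficient (fitness reduction), >= 0 at a true optimum.
    """

    P_opt: float
    factor: float
    s: float

    @property
    def epsilon(self) -> float:
        return self.factor - 1.0

    @property
    def s_over_P_opt(self) -> float:
        return self.s / self.P_opt


def _check_P(P: float) -> None:
    if not (0.0 <= P < 1.0):
        raise ValueError(f"expression fraction P must be in [0, 1), got {P}")


def net_benefit(P: float, params: CostBenefitParams) -> float:
    """Benefit minus cost, ``f * P / (K + P) - P``, at expression fraction P."""
    _check_P(P)
    return params.f * P / (params.K + P) - P


def optimum_cost_benefit(params: CostBenefitParams) -> tuple[float, float]:
    """Optimal expression and fitness of the cost-benefit form.

    Setting the derivative of ``f*P/(K+P) - P`` to zero gives

        P_opt = sqrt(K * f) - K,      s_opt = (sqrt(f) - sqrt(K))**2

    where ``s_opt`` is the net benefit at the optimum (equivalently, the
    fitness lost if the gene is deleted).

    Returns
    -------
    (P_opt, s_opt)
    """
    sf, sk = math.sqrt(params.f), math.sqrt(params.K)
    P_opt = sk * sf - params.K
    s_opt = (sf - sk) ** 2
    return P_opt, s_opt


def metabolic_form(P: float, K: float) -> float:
    """Relative flux ``P / (K + P / (1 - P))`` of the unsaturated linear pathway.

    ``K = C1 / C2`` is the cost (mass per unit activity) of the focal enzyme
    relative to the rest of the pathway; the ``P / (1 - P)`` term is the
    compensation of the other enzymes, whose levels scale as ``1 - P``.
    """
    if K <= 0.0:
        raise ValueError(f"K must be positive, got {K}")
    _check_P(P)
    return P / (K + P / (1.0 - P))


def metabolic_optimum(K: float) -> tuple[float, float]:
    """Optimum of the metabolic form: ``P_opt = sqrt(K)/(1+sqrt(K))``, ``s_opt = 1/(1+sqrt(K))**2``."""
    if K <= 0.0:
        raise ValueError(f"K must be positive, got {K}")
    sk = math.sqrt(K)
    return sk / (1.0 + sk), 1.0 / (1.0 + sk) ** 2


def compare_forms(K: float) -> tuple[float, float]:
    """Fractional differences in (P_opt, s_opt) between the two forms at ``f = 1``.

    Both differences are non-negative (the metabolic form sits slightly above
    the cost-benefit form), vanish as ``K -> 0``, and are about 1-2% at
    ``K = 0.01`` -- the sense in which the cost-benefit form is "the same
    model" as the linear pathway.  ``K = 0`` is accepted as the limit (0, 0).
    """
    if K < 0.0 or K >= 1.0:
        raise ValueError(f"K must be in [0, 1), got {K}")
    if K == 0.0:
        return 0.0, 0.0
    P_m, s_m = metabolic_optimum(K)
    P_cb, s_cb = optimum_cost_benefit(CostBenefitParams(f=1.0, K=K))
    return (P_m - P_cb) / P_m, (s_m - s_cb) / s_m


def selection_exact(params: CostBenefitParams, factor: float) -> PerturbationResult:
    """Exact fitness loss when expression moves from P_opt to ``factor * P_opt``.

    ``factor = 0`` is gene loss (s equals the optimum net benefit),
    ``factor = 0.5`` a 2-fold reduction, ``factor = 2`` a 2-fold increase.
    """
    if factor < 0.0:
        raise ValueError(f"factor must be >= 0, got {factor}")
    P_opt, _ = optimum_cost_benefit(params)
    P = factor * P_opt
    if P >= 1.0:
        raise ValueError(
            f"perturbed expression factor*P_opt = {P} is not a valid fraction"
        )
    s = net_benefit(P_opt, params) - net_benefit(P, params)
    return PerturbationResult(P_opt=P_opt, factor=factor, s=s)


def selection_quadratic(epsilon: float, P_opt: float) -> float:
    """Small-change approximation ``s = eps**2 * P_opt / (1 + eps)``.

    Leading-order cost of a relative change ``eps`` in expression from the
    optimum of the cost-benefit form, valid when the maximum benefit is well
    above the half-max cost (f > 10*K).  Symmetric in eps at leading order:
    a 1% change in either direction costs ~1e-4 * P_opt.
    """
    if epsilon <= -1.0:
        raise ValueError(f"epsilon must be > -1, got {epsilon}")
    return epsilon * epsilon * P_opt / (1.0 + epsilon)


def reference_costs(epsilon: float, P: float) -> tuple[float, float]:
    """Comparison curves: (linear cost ``|eps| * P``, rate-limiting cost ``|eps|``).

    The linear curve is the cost of a stoichiometrically wasted subunit (no
    incremental benefit, so ``|s| ~ |dP|``); the rate-limiting curve is the
    flux loss if the enzyme carried all flux control (``|s| ~ |dP| / P``).
    Both are upper reference lines, not model outputs.
    """
    if P <= 0.0:
        raise ValueError(f"P must be positive, got {P}")
    return abs(epsilon) * P, abs(epsilon)
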
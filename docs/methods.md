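# Methods

This note records the models implemented in `exprsel`, the assumptions and
parameter choices behind them, the numerical methods, and what the test
suite does and does not establish.

## Common conventions

All expression levels are proteome fractions (dimensionless, summing to 1
over the cell).  When the focal protein's fraction *P* changes, every other
protein is rescaled by a common factor so total protein stays constant —
the compensation a promoter or dosage mutation imposes on a cell whose
total macromolecule concentration is homeostatically fixed.  Fitness is
identified with steady-state flux (or growth rate), and a selection
coefficient is reported as a magnitude: s = 1 − fitness(perturbed)/fitness
(optimum) ≥ 0.  Perturbations are parameterized by the multiplicative
factor x = P/P_opt (so gene loss is x = 0) or its relative form ε = x − 1.

## Cost-benefit and metabolic forms (`core_forms`)

The cost-benefit form w(P) = f·P/(K+P) − P has two parameters: the maximum
benefit f ∈ (0, 1] (1 for an essential gene; values down to ~1e-5 are the
weakest benefits selection can maintain) and the half-max investment
K ∈ (0, f) (at least 2e-7, one protein copy per cell in a small bacterium).
Its optimum is P_opt = √(Kf) − K with net benefit s_opt = (√f − √K)².
The metabolic form P/(K + P/(1−P)) is the exact steady-state flux of an
unsaturated reversible linear pathway with the 1−P compensation; its
optimum is √K/(1+√K).  `compare_forms` quantifies their agreement (both
fractional differences ≤ 2% at K = 0.01, vanishing as K → 0); all sweeps
use the f-scaled cost-benefit form, the metabolic form serving as the
bridge to pathway mechanics.

The small-change approximation s ≈ ε²·P_opt/(1+ε) is used only where the
benefit dominates the cost (f > 10·K).  Its advertised 2-fold accuracy
envelope is verified for 2-fold and 1% changes; for strong *reductions*
(ε ≲ −0.75) at marginal f/K the approximation overshoots by more than
2-fold and should not be trusted — the exact `selection_exact` is cheap and
preferred there.

## Two-step Michaelis–Menten pathway (`mm_pathway`)

Boundary conditions: S = 2 mM, E = 1 mM, both steps mildly favorable
(Keq = 10), one shared Michaelis constant Km for all four saturation terms,
and the focal enzyme 100× more active per unit mass than the other
(V1 = 100·P, V2 = 1 − P) so its optimal expression is moderate.  For each P
the intermediate concentration I is the unique root of
flux1(I) = flux2(I) on the thermodynamic bracket (E/Keq2, S·Keq1), found by
Brent's method (xtol 1e-12 mM); the residual is strictly monotone in I, so
the root always exists and is unique.

The intermediate-dilution cost divides the flux by 1 + I·c with
c = 1/(mw_ratio · 4 mM): an intermediate mw_ratio-fold lighter than an
enzyme diluting a 4 mM pool of protein monomers.  mw_ratio = 100 is the
standard case; 10 is the deliberately expensive variant.  Because the
dilution factor divides both step fluxes equally, the same I solves the
costed and costless systems.

Optimization scans the grid P = 5e-4 … 0.5 in steps of 5e-4 and reports the
grid argmax (percent values rounded to one decimal); an optional Brent
refinement between the argmax's neighbors is provided and is used for
sub-percent perturbations, where the up-to-0.27% offset of the grid argmax
from the true optimum would otherwise contaminate an ε = 1% signal.
Perturbations re-solve the steady state at factor·P_opt with the other
enzyme recomputed from its 1 − P share.  A `focal_step = 2` option puts the
focal enzyme (still the high-activity one, keeping its expression moderate)
at the second step; it gives closely similar perturbation costs
(0.57/0.52 vs 0.59/0.53 per P_opt for 2-fold changes at Km = 1).

## Growth model (`growth_model`)

Twenty amino acids, usage fractions f_i (Σf_i = 1), each synthesized by one
enzyme with unsaturated reversible kinetics (substrate 1, equilibrium
constant 10, rate r_i): production_i = E_i·r_i·(1 − A_i/10).  A template-free
"ribosome" (rate 1) incorporates each amino acid as a first-order step, so
growth is g = R/Σ(f_i/A_i).  Steady state balances g·f_i against
production_i.  Substituting A_i(g) = 10·(1 − g·f_i/(E_i·r_i)) reduces the
20-dimensional balance system to one scalar equation in g, solved by
bracketed root-finding on (0, min_i E_i·r_i/f_i); this has the same fixed
point as a least-squares search over the A_i but converges unconditionally.
An allocation whose capacity bound is reached before the balance closes is
reported as infeasible (an enzyme cannot keep up).

Allocation optimization exploits the symmetry of amino acids 2–20 (equal
f_i, r_i ⇒ equal E_i at the optimum) to reduce to two free variables
(R, E_1), maximized by Nelder–Mead from four starting points with
infeasible trial points penalized; the fully symmetric instance
(f_i = 1/20, r_i = 5) has the closed-form optimum R = √2 − 1,
g = 10R(1−R)/(1+R) ≈ 1.7157, which the optimizer matches to 1e-6 and the
steady-state solver to 1e-8 relative.  Focal perturbations rescale *all*
other proteins, ribosome included, by (1 − x·E_1)/(1 − E_1).  The half-max
expression K (the level below P_opt giving g_opt/2) is found by bisection
on the downward branch; across random settings P_opt ≈ 3·K.

### Random parameter settings (`synthetic_params`)

One setting draws the focal usage fraction f_1 = 2^{N_1}/Σ2^{N_i} from 20
standard normals (a heavy-tailed share, median ≈ 0.043, range roughly
0.01–0.4 over many draws), the remaining 19 usages equal; the focal enzyme
rate uses an independent normal vector, identically transformed and
rescaled so the 20 rates average 5 (enzymes typically 5-fold faster or
lighter than the ribosome).  The default sweep is 100 settings, drawn from
a seeded numpy PCG64 generator so every run is reproducible; the summary
statistics of the sweep (medians of the focal optimum ≈ 0.026–0.032 and of
the halving cost ≈ 21%) are stable across seeds at this sample size, while
per-setting extremes are not.  These draws emulate between-gene variation
in amino-acid usage and enzyme efficiency only; they contain no
condition-dependence, no correlated usage across amino acids, and no
regulatory response, so passing tests bound what selection *at least* sees
in a static environment, not how real expression evolves under regulation.

The (f, K) grid for cost-benefit sweeps is log-spaced (10 points per
decade; f ∈ [1e-5, 1], K ∈ [2e-7, 0.1]), keeping net-beneficial points
(K < f) whose optimum lies in [5e-6, 0.03], the expression range covering
>95% of fitness-relevant proteins in *E. coli* and budding yeast.  The
correlation summary of the halving cost with P_opt vs with net benefit is
computed on log10 scale (both quantities span decades); its exact values
are grid-dependent, so only the comparison (expression beats importance)
is asserted, not particular r values.

## Metabolic control analysis (`mca`)

F ∝ Π P_i^{C_i} with ΣC_i = 1 for purely metabolic networks (doubling all
enzymes at fixed metabolite levels doubles all rates).  With proportional
compensation the focal protein's flux is P^C(1−P)^{C_tot−C}, optimal at
P = C when C_tot = 1, giving s = |−ε + ln(1+ε)|·P_opt (natural log — the
small-ε limit 0.5·ε²·P_opt fixes the base), about half the cost-benefit
coefficients.  For C_tot > 1, over-expression costs scale ∝ C_tot; no
closed form exists for the downward direction, which is left at the
C_tot = 1 value (a documented caveat, conservative for a lower bound).
`useless_protein_cost` (1 − (1−f_U)^{C_tot}, equal to f_U at C_tot = 1)
anchors the linear cost term.

## Population genetics (`evolution`)

Plain nearly-neutral arithmetic: selection beats drift when Ne·|s| > 1;
maintaining a gene against a 1000-fold mutational asymmetry (a 1 kb target
vs single-site reversion) inflates the drift threshold by ln(1000) ≈ 7;
deleterious alleles equilibrate at μ/s.  Defaults: Ne = 1e6, μ = 2e-10 per
nucleotide per generation, 1 kb genes, minimum expression 5e-6.  The
duplication ledger compares the dosage cost of a 2-fold change
(≥ 0.2–0.5·P) with the mutational-robustness benefit of a second copy
(≈ the gene's total mutation rate, 2e-7): the cost wins for any gene above
the expression floor.

## Problem sizes and determinism

The standard runs are desk-scale: the MM grid has 1,000 points per setting,
the growth sweep 100 settings (a few seconds on one CPU), and property
tests use 10–25 random parameter draws with fixed seeds; the brute-force
optimum oracle uses 1e6-point grids.  All randomness flows through explicit
integer seeds; rerunning any sweep with the same seed and configuration
produces byte-identical output files (provenance headers record seed,
config hash and package version).

## Known limitations

* Monomeric/homomeric proteins only: subunits of tight heteromeric
  complexes gain no benefit from unilateral over-expression, so their cost
  is linear (|s| ≈ |ΔP|) — provided as a reference curve, not modelled.
* No stochastic gene-expression noise, no condition-dependent benefits, no
  toxic or inhibitory intermediates, no redundancy beyond the quadratic
  dosage argument.
* The growth model's optimal expression is unrealistically sensitive
  (P_opt ≈ 3·K implies a median 21% cost for halving — higher than
  observed haploinsufficiency rates); it brackets the cost-benefit form
  from above rather than describing typical genes.
* The MCA treatment takes control coefficients as locally constant and
  C_tot = 1; it is a lower-bound device, not a network inference method.
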
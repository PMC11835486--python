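# Methods

## The kinetic model

`mircompete` models pre-miRNA maturation as mass-action kinetics in a single
well-mixed compartment. Each pre-miRNA species *i* exists as free hairpin
`P_i`, transient Dicer complex `PD_i`, irreversibly stalled complex `S_i` or
mature miRNA `M_i`; a single pool of free Dicer `D` is shared by all species
(concentrations in nM, time in s):

    dP_i/dt  = k_b PD_i − (k_a + k_c) P_i D
    dPD_i/dt = k_a P_i D − (k_b + k_d) PD_i
    dS_i/dt  = k_c P_i D
    dM_i/dt  = k_d PD_i
    dD/dt    = Σ_i [(k_b + k_d) PD_i − (k_a + k_c) P_i D]

Per species, `k_a` (s⁻¹ nM⁻¹) is Dicer association, `k_b` (s⁻¹) dissociation,
`k_c` (s⁻¹ nM⁻¹) irreversible stalling and `k_d` (s⁻¹) dicing. The free-Dicer
equation sums over species so that the two conservation laws —
`P_i + PD_i + S_i + M_i = P0_i` per species and `D + Σ_i (PD_i + S_i) = D0` —
hold exactly; both are asserted in the tests at 10× solver tolerance.
Production, transport and degradation of pre-miRNA are deliberately outside
the model: the simulated horizon (minutes to tens of hours) is assumed short
against those processes.

Default parameters are the fitted wild-type and short-loop (let-7) rate sets:

| rate | wild-type | short-loop |
|------|-----------|------------|
| k_a  | 0.0053    | 0.0020     |
| k_b  | 0.1340    | 0.2902     |
| k_c  | 0.0122    | 0.0343     |
| k_d  | 10439     | 0.0707     |

with `P0 = 1 nM`, `D0 = 5 nM` as the in-vitro reference condition.

### Closed-form oracle

When free Dicer is never exhausted, the fate of one pre-miRNA molecule is a
first-passage problem whose absorption probability into the mature state is

    q = k_a k_d / (k_a k_d + k_c (k_b + k_d)).

`closed_form_diced_fraction` exposes this, and `stall_demand` computes
`Σ_i (1 − q_i) P0_i`, the Dicer permanently consumed if no species is
supply-limited; whenever that is below `D0` the integrator must reproduce
`M_i(∞) = q_i P0_i`, which is the package's main numerical oracle
(agreement to 1e−4 is a test). For the wild-type rates `q ≈ 0.3029`.

### Numerical integration

The system is stiff: `k_d ~ 1e4 s⁻¹` coexists with binding timescales of
~10–10⁴ s. The default integrator is scipy's implicit **BDF** with
`rtol = 1e-8`, `atol = 1e-10`. The switching LSODA solver (selectable via
`method=`) reproducibly stalls on one workload case (the 10× dicing-rate
species at 1.55 nM Dicer): after the transient the solution is flat but the
complex keeps a ~1e5 s⁻¹ eigenvalue alive, and LSODA's non-stiff mode grinds
at stability-limited steps without switching. BDF integrates every case in
well under a second with results identical to the closed form.

Steady state is declared when `max |dy/dt| < 1e-9 nM/s`, probed at 25
logarithmically spaced times up to a hard cap of 180 000 s (3000 min, the
horizon used for all steady-state read-outs). Negative concentrations are
never clipped silently: values below −10× the tolerance scale raise an
error. Species with `P0 = 0` are identically zero by structure, and solver
roundoff (~1e-24) on those components is scrubbed so knockouts read exactly
zero. The "absence of competition" control integrates each species alone
with the full `D0`, the only interpretation that leaves single-species
dynamics unchanged; `SteadyState.D` is then per-species.

## Fitting

The observable is the diced fraction `M(t)/P0`. The fit minimizes the sum of
squared errors over the time grid while pinning `Kd = k_b/k_a` to its
experimentally reported value (25.4 nM wild-type, 147.7 nM short-loop), so
the free parameters are `(k_a, k_c, k_d)` with `k_b = Kd·k_a` substituted
inside the objective — the returned ratio is exact by construction. The
search runs in log10 space with bounds `[1e-5, 1e5]` per rate (rates span
eight orders of magnitude across the two fitted conditions), using an
in-package (μ/μ_w, λ)-CMA-ES (population 10, σ₀ = 0.8, seed 1234 by
default) followed by a bounded Nelder–Mead polish: the SSE landscape has a
narrow curved valley that the evolution strategy descends slowly, and the
simplex finishes the job cheaply. ODE solves inside the objective use
`rtol = 1e-6`, which bounds SSE error near 1e-13, far below data noise; a
solver failure on a candidate returns a 1e6 penalty instead of raising, so
the optimizer can keep ranking.

**Identifiability.** When `k_d ≫ k_b` the curve determines only the plateau
`q` and the net depletion rate `(k_a + k_c − k_a k_b/(k_b+k_d))·D`; raw
`k_d` is bounded below but not above. Different seeds legitimately land on
slow-`k_d` solutions with indistinguishable curves. Recovery is therefore
judged on the curve (max abs error < 0.01 noiseless), the plateau (2%) and —
at the default seed — the depletion-rate combination (5%), never on raw
`k_d`.

## Competition experiments

The eight-species panel takes the wild-type rates and raises one rate per
species 10-fold (`*_hi`) or 20-fold (`*_2hi`), each species at 1 nM. Its
total stall demand is ≈ 5.0 nM, so 8 nM Dicer is "abundant" (shared and
isolated runs agree to 1e-3 nM) while 1.55 nM sits well inside the
competitive regime and is the fixed condition for perturbation experiments.
Grids default to 25 log-spaced rate scales, 40 Dicer points and 21
pre-miRNA points (all configurable; tests use coarser grids). Fold changes
are ratios of steady mature miRNA to a named reference condition (8 nM
Dicer for the Dicer sweeps; 5 nM per-species pre-miRNA with 15 nM Dicer for
the joint sweep; the all-1-nM baseline for perturbations). A zero reference
yields a missing value, never infinity. The minimum Dicer needed to reach a
0.5 fold change is located by a coarse grid scan plus bisection to 1e-3 nM,
since a grid-only answer would be resolution-dependent.

## The BPP affinity proxy

TRBP, which loads pre-miRNAs onto Dicer, prefers strongly paired stems; the
package scores that tendency per miRNA. From a hairpin record (sequence,
dot-bracket, mature-arm intervals) it extracts the mature duplex — the two
arm subsequences plus exactly those structure pairs with one end in each
arm, re-indexed to arm-local coordinates — then computes inter-strand
pairing probabilities with a pluggable engine:

- the built-in **reference engine** evaluates the partition function over
  all non-crossing (antiparallel-nested) inter-strand matchings with unit
  weight per Watson–Crick/GU pair, by dynamic programming; it is exact and
  is tested against brute-force enumeration on all duplexes up to length 6;
- the **Vienna engine** substitutes the Turner-model RNAcofold ensemble
  (inter-strand block of the two-strand pair-probability matrix) when the
  ViennaRNA python bindings are importable.

Positions are laid on a cleavage-centred axis: 5′-arm positions negative
(loop-proximal = −1), 3′-arm positions positive (loop-proximal = +1), 0 an
empty marker. A position covered by a recorded bond takes that bond's
probability (on both strands); an uncovered position takes the mean
probability over all candidate partners on the opposite strand
(`fill="per-partner-mean"`, the default, computable per miRNA in
isolation). An alternative cohort fill — the mean of recorded-bond values at
the same axis position across the cohort — is available via `fill="none"` +
`apply_cohort_fill`. The AUC is the trapezoidal integral of the curve over
the axis; `auc_norm` (AUC/span) is a mean pairing probability in [0, 1],
comparable across duplex lengths. Records failing validation are excluded
with a per-record reason, mirroring how registry entries without structures
are dropped. Only inter-strand pairing enters the score; intra-strand
pairing within one arm is ignored.

## Association statistics

Per-genotype associations are ordinary least squares of log10 expression on
AUC with Pearson r and a two-tailed p from the t distribution (n − 2 df);
zero-expression miRNAs are excluded from the log transform with a logged
reason. The slope comparison is deliberately the formula as printed in the
source analysis, `t = (β₁ − β₂)/(SE₁ + SE₂)`, with df = n₁ + n₂ − 4 (two
parameters per regression); because `SE₁ + SE₂ ≥ √(SE₁² + SE₂²)` this is
conservative relative to the conventional quadrature form, which is
available as `variant="quadrature"`. The published slope/SE pairs
(1.49 ± 0.449 vs 1.89 ± 0.427) evaluate to t ≈ −0.457 under the printed
formula, not the published t = −2.720971; the package records the
discrepancy and reproduces only the p-from-t computation
(t = −2.720971, df = 84 → p = 0.00791), which is internally consistent.
The fold-change association joins expression fold changes
(condition/reference) with AUC, removes fold changes above a cap (default
4) before regressing — the cap applies only to this analysis, not to the
per-genotype regressions — and reports the retained-row association plus a
per-miRNA detail table with a `filtered` flag.

## Synthetic data

The generators define the study conditions and are first-class, seeded and
bit-reproducible:

- **Dicing time courses** emulate the in-vitro assay: 1 nM pre-miRNA, 5 nM
  Dicer, 60 min, with additive Gaussian noise on the fractions (default sd
  0.02, roughly gel-quantification error), clipped to the [−0.05, 1.05]
  validity band so small negative noise is reported, not hidden. The default
  grid is 20 log-spaced points from 15 s to 60 min: the wild-type depletion
  transient has τ ≈ 11 s, so a grid that only samples late times carries no
  information about the depletion rate; gel time courses likewise
  concentrate early samples.
- **Hairpins** are stem–loop–stem constructs whose stem positions carry an
  inter-arm pair with probability θ (Watson–Crick, 10% GU) and a mismatch
  otherwise; arm lengths 18–25 nt, loops 4–12 nt. Mean AUC is strictly
  increasing in θ, which is both a sanity check and the gradient the
  association tests exploit.
- **Expression tables** draw log10 expression = α_g + β_g·AUC + N(0, sd)
  per genotype, mirroring the fitted regressions (default generative slopes
  1.49 and 1.89); expression is 10^(log10), in arbitrary normalized units.
  No count-level noise model is imposed since the analysis operates on
  log10 expression directly.

What the generators do **not** emulate: real hairpins have bulges, internal
loops and sequence biases beyond independent per-position pairing; real
expression has count noise, normalization artefacts and shared regulation;
real dicing data have correlated gel errors. Passing recovery tests
therefore demonstrates that the estimators are correct and well-calibrated
under the stated generative model, not that the biological conclusions
transfer to any particular dataset.

## Problem sizes in the shipped tests

The test suite and acceptance script favour exact small instances: duplex
enumeration to length 6, hairpin cohorts of 40–60, expression cohorts of 44
per genotype with 200 replicates, CMA-ES budgets of 300–800 evaluations
(the Kd ratio is exact at any budget; the curve-recovery assertions use the
larger budgets), and coarse 4–5 point Dicer grids for the ordering
properties. All grids and budgets are parameters, so larger reproductions
are one argument away.

## Known limitations

- The stalled complex is a modelling device for the observed dicing
  ceiling, not a described biochemical species; interpretations that hinge
  on `S` specifically should be treated with care.
- The slope-comparison test inherits the printed (conservative) denominator
  by design; use the quadrature variant for a calibrated test.
- The reference cofold engine weighs all canonical pairs equally; AUC
  values are comparable within one engine but not across engines.
- CMA-ES recovery of individual rate constants is limited by the
  identifiability structure discussed above; only curve-level quantities
  are meaningful fit outputs.
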
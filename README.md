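# mircompete

Modelling competition between pre-miRNAs for a shared pool of Dicer — and
what that competition does to the composition of the mature miRNA pool.

During miRNA maturation, many pre-miRNA hairpin species are cleaved by the
same limited pool of the enzyme Dicer. `mircompete` implements a mass-action
model of this process, the machinery to fit its rate constants to dicing
time courses, simulation experiments that probe the competitive regime, a
base-pair-probability (BPP) proxy for TRBP/Dicer affinity computed from
hairpin structures, and the statistics that associate that proxy with miRNA
expression across genotypes. Seeded synthetic-data generators supply every
input, so the whole pipeline runs end to end with no downloads.

## The model

For each pre-miRNA species *i* (free hairpin `P_i`, Dicer complex `PD_i`,
stalled complex `S_i`, mature miRNA `M_i`) sharing free Dicer `D`:

    dP_i/dt  = k_b PD_i − (k_a + k_c) P_i D
    dPD_i/dt = k_a P_i D − (k_b + k_d) PD_i
    dS_i/dt  = k_c P_i D
    dM_i/dt  = k_d PD_i
    dD/dt    = Σ_i [(k_b + k_d) PD_i − (k_a + k_c) P_i D]

Dicing (`k_d`) returns Dicer to the pool; stalling (`k_c`) sequesters it
permanently, which is what makes the pool exhaustible and the species
interdependent. When Dicer is never exhausted, the steady-state diced
fraction has the closed form

    q = k_a k_d / (k_a k_d + k_c (k_b + k_d)),

used throughout as an independent oracle for the integrator. Rate fitting
minimizes the SSE between model and measured diced fractions under the
constraint `k_b/k_a = Kd` (25.4 nM wild-type, 147.7 nM short-loop), using an
in-package CMA-ES in log-rate space. The affinity proxy scores each
miRNA's mature duplex by the area under its per-position base-pair
probability curve (AUC); per-genotype regressions of log10 expression on
AUC are compared with the slope t statistic
`t = (β₁ − β₂)/(SE₁ + SE₂)`. See `docs/methods.md` for assumptions,
numerical choices and limitations.

## Worked example

```python
from mircompete import (
    SpeciesSpec, SystemConfig, WT_RATES,
    closed_form_diced_fraction, run_to_steady_state,
)

config = SystemConfig(species=(SpeciesSpec("let-7-wt", 1.0, WT_RATES),), D0=5.0)
ss = run_to_steady_state(config)
print("steady M = %.4f nM, closed form q = %.4f"
      % (ss.M[0], closed_form_diced_fraction(WT_RATES)))
```

prints

```
steady M = 0.3029 nM, closed form q = 0.3029
```

— about 30% of the wild-type pre-miRNA matures; the remaining 70% ends up
in stalled complexes, each one permanently consuming a Dicer. With eight
competing species (`examples/competition_panel.py`) this stall demand is
what turns 1.55 nM Dicer into a competitive regime: knocking out the
fast-stalling species frees enough Dicer to raise every other species'
mature output by up to 2.3-fold, while overexpressing it suppresses them to
0.24–0.30 of baseline.

The `examples/` directory has one short script per capability:
single-species kinetics, constrained rate fitting, the 8-species
competition panel with perturbation matrices, BPP-AUC scoring of hairpins,
and the two-genotype expression association.

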
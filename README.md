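# phagevolve

Eco-evolutionary dynamics of the two routes by which bacteria escape a
virulent phage: **constitutive** surface (receptor) mutation, which is
always costly, and **inducible** CRISPR-Cas immunity, which is costly
only under infection. The package is for quantitative microbiologists
and theorists who want to simulate serial-transfer infection
experiments, predict which resistance route wins under a given inoculum,
phage dose and carrying capacity, and fit the key rates to clone-typing
data.

## The model

A batch culture holds sensitive cells *S*, surface mutants *R*,
CRISPR-immune cells *C*, double mutants *D* and free phage *V*. With
logistic factor *g* = 1 − *N*/*K* and mutation flux *M*(*X*):

    dS/dt = r_S g S − aVS − M(S) − A aV S + L C
    dR/dt = r_R g R + M(S) + L D
    dC/dt = r_C g C + A aV S − M(C) − L C
    dD/dt = r_D g D + M(C) − L D
    dV/dt = B aVS − aV(S + C) − m_v V

where r_S = r, r_R = r_D = e^(−c_R) r, and r_C = e^(−τaV) r. Surface
mutation arises during replication (rate μ per replication); spacer
acquisition requires phage exposure (rate *A·aV*). Because double
resistance protects no better than single resistance, epistasis is
negative and the linkage disequilibrium LD = f_S f_D − f_R f_C goes
negative as resistance spreads. The package adds serial-transfer
protocols and factorial design sweeps, selection-coefficient and LD
diagnostics, an exact (Gillespie) and tau-leaping stochastic
counterpart, a synthetic clone-phenotyping data generator (two-phage
streak assay: sensitive / sm / CRISPR), and multinomial
maximum-likelihood inference of {μ, A, c_R, τ}. See `docs/methods.md`
for assumptions, switches and limitations.

## Worked example

Which resistance route dominates after one day, as a function of
inoculum size?

```python
import phagevolve as pv

params = pv.ModelParams.paper_defaults()   # r=1/h, K=1e8/ml, mu=1e-4, A=5e-4, ...
design = pv.bundled_design("inoculum_sweep")  # S0/K in {10%..0.01%}, V0=1e6/ml
table = pv.run_design_grid(design, params)
print(table[["treatment", "inoculum_fraction", "f_R", "f_C"]]
      .round(3).to_string(index=False))
```

```
  treatment  inoculum_fraction   f_R   f_C
   inoc_0.1              0.100 0.282 0.714
  inoc_0.01              0.010 0.410 0.588
 inoc_0.001              0.001 0.563 0.436
inoc_0.0001              0.000 0.659 0.341
```

(the smallest inoculum fraction, 0.0001, rounds to 0.000 in the
3-decimal display)

Large inocula reach carrying capacity after few doublings, so few
receptor mutants arise and CRISPR immunity dominates (f_C = 0.71 at
10%); small inocula replicate ~13 generations and surface mutants take
over (f_R = 0.66 at 0.01%). The same sweep is available from the shell:

```sh
phagevolve sweep --design inoculum_sweep --out out/
phagevolve figures out/results.csv --out out/
```

Other subcommands: `simulate` (single trajectory), `ssa` (stochastic
replicates), `metrics` (frequencies/LD/selection from a trajectory),
`synth` (synthetic clone tables + CFU/PFU counts), `fit`
(maximum-likelihood fitting, `--bootstrap N` for intervals). Every
command writes a JSON run manifest with the fully resolved
configuration and output hashes.

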
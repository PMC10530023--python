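# Methods

## The model

`phagevolve` simulates a well-mixed batch culture of *Pseudomonas
aeruginosa*-like bacteria exposed to a virulent phage, tracking five
compartments: sensitive cells `S`, surface (receptor) mutants `R`,
CRISPR-immune cells `C`, doubly resistant cells `D` (all cells/ml) and
free phage `V` (phage/ml). Host growth is logistic with a shared
density-dependence factor `g = 1 − N/K`, `N = S+R+C+D`. The default
system is

```
dS/dt = r_S g S − a V S − M(S) − A a V S + L C − m S
dR/dt = r_R g R + M(S) + L D − m R
dC/dt = r_C g C + A a V S − M(C) − L C − m C
dD/dt = r_D g D + M(C) − L D − m D
dV/dt = B a V S − a V (S + C) − m_v V
```

with intrinsic growth rates `r_S = r`, `r_R = r_D = e^{−c_R} r`
(constitutive cost of receptor mutation) and `r_C = e^{−τ a V} r`
(infection-induced toxicity of CRISPR immunity). Phage infect sensitive
cells by mass action `aVS` with burst size `B`; adsorption to CRISPR
hosts removes phage without progeny (the phage sink); adsorption to `R`
and `D` is blocked by the mutated receptor and removes nothing.
`M(X)` is the surface-mutation flux, `A a V` the spacer-acquisition
rate, and `L` the CRISPR-loss rate (`C → S`, `D → R`).

Because double resistance protects no better than either single
resistance while paying the constitutive cost, epistasis between the
two loci is strongly negative; the package quantifies the consequences
through the two-locus linkage disequilibrium `LD = f_S f_D − f_R f_C`
and through selection coefficients (below).

### Parameters

All rates are per hour, densities per ml. Defaults are the reference
parameter set for the PA14/DMS3vir system:

| name  | default | meaning |
|-------|---------|---------|
| `r`   | 1       | maximal per-capita growth rate |
| `m`   | 0       | host background mortality |
| `m_v` | 0       | free-phage decay |
| `a`   | 1e−8    | adsorption rate constant (ml/phage/h) |
| `B`   | 100     | burst size |
| `c_R` | 0.01    | constitutive cost of surface resistance |
| `tau` | 0.01    | CRISPR infection-induced toxicity coefficient |
| `mu`  | 1e−4    | surface-mutation rate (per replication) |
| `A`   | 5e−4    | spacer-acquisition efficiency |
| `L`   | 1e−3    | CRISPR resistance-loss rate |
| `K`   | 1e8     | carrying capacity (cells/ml) |

Time units are taken as hours throughout (`r = 1` with 20-hour growth
periods); rates are convertible if another unit is preferred.

### Structural switches

The literature description of this class of model leaves several
microscopic choices open; each is an explicit switch with a documented
default rather than a silent assumption.

- **`mutation_model`** — `per_replication` (default): mutation flux
  `M(X) = μ r_X g X`, tying mutant supply to replication, which is what
  makes inoculum size matter (fewer doublings to carrying capacity ⇒
  fewer chances to mutate). The alternative `per_capita` (`M(X) = μX`)
  treats the rate as constant per cell per hour.
- **`acquisition_from_R`** — off by default: spacer acquisition requires
  phage entry, and receptor mutants block adsorption, so `D` arises only
  by surface mutation of `C`. On, it adds `R → D` at `A a V`.
- **`rescue_on_acquisition`** — off by default: the acquisition flux
  `A a V S` is booked independently of the lysis flux `a V S`. On, lysis
  becomes `(1−A) a V S` (an adsorbed cell that acquires a spacer is not
  lysed) and phage production uses the same reduced flux. At the default
  `A = 5e−4` the difference is negligible, but the switch makes the
  choice explicit.
- **`L`** is interpreted as loss of CRISPR function (`C → S`, `D → R`);
  reversion of a receptor mutation is biologically implausible. Set
  `L = 0` to disable.

`g` is not clipped at zero in the deterministic model: with `m = 0` and
initial `N ≤ K`, `N` cannot exceed `K` except by solver error, which the
tolerance tests bound. The stochastic simulator does clip (births cannot
be negative) and counts the clipped instants.

## Numerical integration and serial transfers

Batches are integrated with LSODA (stiff-capable; `V` spans ~10 orders
of magnitude across treatments) at `rtol = 1e−8`, `atol = 1e−12`.
Densities below an extinction floor of 1e−30/ml are snapped to zero
after each batch to avoid denormal drift. A serial transfer multiplies
hosts and phage by their dilution factors (default 1:100 for both,
daily, 3 days, 20 h per batch); `K` is a media property and is
unchanged. Trajectories store the pre- and post-dilution states with the
same time stamp and record both indices, so daily "plating" always reads
the pre-dilution state at t = 20, 40, 60 h.

## Bundled designs

- `inoculum_sweep`: S0/K ∈ {10%, 1%, 0.1%, 0.01%}, V0 = 1e6, K = 1e8,
  one 20 h batch. `inoculum_sweep_moi` re-scales V0 to hold the MOI at
  0.1 so the dose channel can be isolated.
- `dose_capacity_grid`: V0 ∈ {1e2, 1e4, 1e6, 1e8, 1e10} × K ∈
  {1e6, 1e7, 1e8, 1e9}, S0 = K/100, 3 transfers. The capacity levels
  span three decades (the experimental glucose range) around the default
  K = 1e8; the top dose is included because the sm-favoured regime
  requires `τ a V0 ≈ 1`, i.e. V0 ≈ 1e10 at the default `τ` and `a`.
- `transfer_dynamics`: the single default 3-transfer condition
  (K = 1e8, V0 = 1e4) used for the LD and selection diagnostics.
- `clone_typing_factorial`: the experimental factorial used for synthetic data
  and inference — doses {1e1, 1e2, 1e3, 1e5, 1e9} × four capacity
  levels, 6 replicates, 24 clones, days 1–3. The low-capacity,
  slow-epidemic treatments are what make the absolute magnitudes of
  `μ` and `A` identifiable; with only high-exposure treatments the
  likelihood is nearly flat along their common-scale direction and only
  their ratio is pinned.

## Population-genetic diagnostics

Genotype frequencies are `f_X = X/N`. The selection coefficient of an
allele is the flux-weighted per-capita *birth/death* rate of carriers
minus that of non-carriers — growth under density dependence and lysis,
excluding mutation, acquisition and loss fluxes, which are supply rather
than selection. For the surface allele carriers are {R, D}; for the
CRISPR allele {C, D}. In the no-supply limit (`μ, A, L → 0`) the
coefficient equals `d/dt logit(f_carriers)` exactly, which is the
property the tests pin. Each coefficient is reported with its growth
and phage-protection components, which sum to the total. Coefficients
are undefined while either allele class is empty; time-integrals
(trapezoid on solver output, zero-width at transfer discontinuities)
skip undefined samples.

The interference analysis sweeps the acquisition efficiency `A` on the
`transfer_dynamics` setup: faster early CRISPR establishment both raises
population-level resistance and drains the phage, so the integrated
selection for surface resistance and its final frequency fall together.

## Stochastic counterpart

`simulate_stochastic` is an exact Gillespie realisation of the same
fluxes at integer copy numbers (density × volume; default 1 ml so
densities equal counts): per-capita births with the logistic factor,
surface mutation as a per-birth Bernoulli(μ) under the default mutation
model, adsorption events with instantaneous burst, independent
acquisition events, CRISPR loss and background deaths; transfers are
binomial thinning. The core is numba-compiled (a 20 h batch at K = 1e6
counts executes ~1e7 events). A tau-leaping variant uses a Cao-style
step bound on the expected relative propensity change (ε = 0.03) with
step-halving on negativity; it agrees with the exact method in
distribution mid-growth but carries the method's known Poisson-overshoot
bias where the logistic boundary freezes the birth channel, so the exact
method is preferred below ~1e6 events.

A caveat established by the package's own experiments: the mean of the
stochastic process is *not* the deterministic solution when the epidemic
is seeded by few phage particles. With V0 = 100 counts the first lysis
events carry ~1 h of exponential timing jitter, and at a sampling time
where the deterministic host density is mid-crash (falling ~30% per half
hour) the run-mean deviates from the ODE by tens of percent however many
runs are averaged. The deterministic model is the large-inoculum,
large-population limit, not the finite-copy-number expectation; the
acceptance suite records this deviation honestly rather than averaging
it away.

## Synthetic observations

The generator emulates the experiment's observation layer, not its biology:
per replicate, 24 clones are assigned genotypes by a multinomial draw
from the deterministic frequencies and pushed through the two-phage
streak assay (plain phage vs anti-CRISPR AcrIF1 carrier). Sensitive
clones resist neither phage, surface mutants both, CRISPR clones only
the plain phage; doubly resistant clones score as surface mutants
because AcrIF1 disables CRISPR while the receptor stays mutated. The
observed classes therefore estimate `(f_S, f_R + f_D, f_C)`, and
inference must (and does) use that mapping. Optional between-replicate
overdispersion is Dirichlet-multinomial with correlation ρ
(variance inflation `1 + (n−1)ρ`); CFU/PFU plate counts get
mean-preserving lognormal noise with CV 0.2 by default (a plating-noise
proxy, not fitted to data).

What the generator does not emulate: demographic stochasticity between
replicate cultures (the truth is the shared deterministic trajectory
unless the stochastic simulator is used), assay misclassification,
resistance-losers scored as sensitive, and phage evolution. Passing
recovery tests therefore show the estimator is consistent under the
observation model, not that real cultures are this well behaved.

## Inference

`fit_parameters` maximises the multinomial log-likelihood of a clone
table over a subset of {μ, A, c_R, τ}, with class probabilities from the
deterministic model (a mean-field approximation chosen for desk-scale
cost). Optimisation is multi-start L-BFGS-B in log10-parameter space
with bounds [1e−8, 1e−1] for μ and A (rates span orders of magnitude and
must stay positive); one start at the centre of the log-bounds box, the
rest drawn uniformly from the seed. Probabilities are floored at 1e−12
before logging. Nonparametric bootstrap over replicates (percentile
intervals) is available. Joint identifiability of τ and c_R from clone
fractions alone is not guaranteed — both enter through growth costs —
and should be checked by profiling before trusting a joint fit.

## Problem sizes

The test and acceptance runs use the emulated experiment's own sizes
(24 clones × 6 replicates × 3 days; 200 stochastic runs at K = 1e6
counts) and deliberately small synthetic cases elsewhere (tau-leap
cross-checks at K = 2e3; recovery-vs-replication at 8 datasets per arm,
single free parameter) — chosen as the smallest sizes at which the
distributional assertions have useful power.

## Known limitations

- No phage evolution (escape mutants, dynamic Acr carriage), single
  phage species, no spatial structure, no explicit latent period.
- Several microscopic details are left open by the verbal description
  of this model class (whether acquisition subtracts from the lysis flux,
  whether loss applies to both CRISPR-carrying classes, how mutation
  scales); each is exposed as a switch and defaulted as documented
  rather than silently assumed.
- Selection coefficients are reported per hour; per-generation scaling
  (divide by the realised growth rate) is left to the caller.
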
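# Methods

## Model

`agerep` integrates continuous-time replicator dynamics over a discretized
age structure.  Time is measured in units of one age class; during one unit
each individual plays (a fraction `τ` of) one game round whose outcome sets
its fertility `f_j^i` and death probability `d_j^i`.  Survivors of a unit
move to the next class, so the deterministic skeleton of the model is a
Leslie projection with state-dependent entries, and the continuous dynamics
are its normalized flow: per-strategy age rows, strategy frequencies and the
total size `n` evolve by the equations in the package README.  The key
assumption inherited from this construction is that the population state
changes slowly on the timescale of a single game round, so rates evaluated at
the start of a unit are good for the whole unit.

Both coordinate systems (strategy-major `Sa`, age-major `Sb`) are exact
re-parameterizations of one underlying count system

    ṅ_j^0 = Σ_z n_j^z f_j^z (1 − n/K) − n_j^0,
    ṅ_j^i = s_j^{i−1} n_j^{i−1} − n_j^i,

and the test suite holds all three representations together: trajectories of
`Sa` must match the normalized count system and, mapped through the
coordinate transforms, the trajectories of `Sb`.

Density dependence multiplies fertility — never survival — by `(1 − n/K)`.
The factor is deliberately left unclamped when `n > K` transiently, matching
the model equations; `n` cannot grow without bound because the factor turns
negative.  At any rest point of the size equation with mean fertility
`f̄ > 0`, `n = K (1 − (1 − s̄)/f̄)`.

## Euler–Lotka conventions

Two discount timings of the Euler–Lotka sum are implemented, because the
classical 1-based-age renewal sum and the 0-based-class Leslie matrix differ
by one power of the growth multiplier:

* `timing="start"` (default): `f^0 + Σ_{i≥1} e^{−ir} f^i l^i`, the renewal
  sum with reproduction credited at the start of the class interval (the
  infant term undiscounted).
* `timing="end"`: `Σ_{i≥0} e^{−(i+1)r} f^i l^i`, reproduction credited at
  the following census.  This is exactly the characteristic polynomial of
  the Leslie matrix, and it is the form satisfied (value 1 at `r = ln λ`)
  both by the dominant eigenpair and by the attracting manifold of the
  dynamic systems.

At the attractor the start-timing sum evaluates to `λ` itself; the property
suite pins both identities.  Quantitative statements about the dynamics
("the Euler–Lotka equation holds at steady state") therefore use the end
timing; the start form is kept because it is the convention in which
single-equation hand calculations (e.g. `4e^{−2r} = 1`) are usually posed.
The root solver brackets `r` in `[−50, 50]` and refines with Brent's method
to `|LHS − 1| < 1e−10`; inputs with no age-dependent term (only `f^0 > 0`)
are rejected as degenerate rather than returning an arbitrary root.

Dominant Leslie eigenpairs are computed by power iteration from the uniform
vector (sup-norm tolerance 1e−12, at most 1e5 iterations).  Imprimitive
schedules — reachable reproductive ages with a common divisor > 1, e.g. a
single reproductive class — are detected by that gcd criterion, iterated on
the shifted matrix `L + I` (same eigenvectors, spectrum moved off the tied
circle), and flagged in the result, since their stable structure is not
attracting.  `numpy.linalg.eig` is used only as an independent oracle in the
tests.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `τ` | fraction of individuals playing one round per time unit | 1 | folded into the vital rates; `τ d_j^i > 1` is rejected |
| `K` | carrying capacity (maximal load), individuals | — (`inf` = density-free) | scales fertility via `(1 − n/K)` |
| `m + 1` | number of age classes | scenario-specific | terminal-class survival forced to 0 when the closed-last-class flag is set |
| `survivors_reproduce` | multiply fertility by single-round survival `(1 − d)` | off | trade-off variant; not used by the case study |
| `k` | brood size (offspring per female), sex-ratio model | 6 | see below |

The case-study brood size is a free parameter of the scenario; 6 is a
realistic mid-range clutch for an iteroparous vertebrate-like schedule and
the long-run primary sex ratio is insensitive to it (the acceptance suite
re-runs the scenario at k = 4, 6 and 10).

## The sex-ratio case study

The packaged scenario uses three strategies P = (0.05, 0.55, 0.95), 26 age
classes, female survival 0.95 for classes 0–9 and 0.80 from class 10, male
survival 0.88 for classes 0–14 and 0.72 from class 15 (terminal class 0 for
both), female activity window [8, 15], male window [8, 20] (both ends
inclusive), G(0) = (0.9, 0.05, 0.05), infant sex ratios (0.7, 0.1, 0.1),
each non-infant class at frequency 0.001 (so 0.025 of each gene's carriers
are non-infant), non-infant sex ratios (0.9, 0.8, 0.8), n(0) = 40,
K = 10 000.  Two readings were fixed once and documented here: "survival
0.95 until age 10" is inclusive-exclusive (class 10 already has the lower
survival), and the separately given infant sex ratios apply to class 0 only,
with the 0.9/0.8 values for every class ≥ 1.

Genetics is deliberately minimal: a haploid gene with the 1/2 transmission
factor carried inside the payoffs; no explicit diploid bookkeeping.

## Numerical integration

Integration uses `scipy.integrate.solve_ivp`.  The default method is the
explicit adaptive `DOP853` pair (rtol 1e−8, atol 1e−10), appropriate for the
generic replicator systems.  The sex-ratio case study is stiff during its
cohort-front transient — the sex ratio of a nearly-empty age class relaxes at
rate `a_j^{i−1}/a_j^i`, which spikes while the growing cohort passes — so the
packaged scenario and the CLI runner select `LSODA`; explicit pairs overshoot
the `[0, 1]` bounds there and abort.  The convergence test halves both
tolerances on the case study and requires final-state agreement below 1e−5.

State layout: simplex rows are integrated over classes 1..m with class 0
recovered as the residual `1 − Σ`; a negative residual beyond −1e−9 aborts,
smaller excursions are clipped to 0.  Sex ratios may drift outside `[0, 1]`
by at most 1e−9 (clipped) before the run aborts.  Divisions in the age-major
system and in the sex-ratio equations are guarded at `ε = 1e−12` per class;
the recommended practice, followed by the engine, is to integrate the
strategy-major system and transform, keeping the age-major right-hand side
for verification and for age-major analyses at interior states.  After
integration, simplex drift per snapshot in `(1e−12, 1e−8]` is corrected by
rescaling (and counted in the trajectory metadata); larger drift is an
error.  Steady-state termination stops at the first time the sup-norm of the
packed derivative falls below 1e−9.

Problem sizes: the case study integrates 157 coupled ODEs and reaches the
steady-state threshold before t ≈ 1000 (about one second of CPU); the
verification fixtures use 1–5 strategies and up to 7 age classes, where the
count-system and transform oracles are cheap to hold at 1e−6.

## Synthetic scenarios

`fixtures` generates all test inputs programmatically: seeded uniform vital
rates (closed last class, at least one positive fertility), interior
strategy-major states (normalized positive uniforms, every entry ≥ 1e−3 so
transforms and divisions are well-defined), constant-payoff models, the
packaged case study, and a suite of degenerate scenarios (single class,
single strategy, equal payoffs, sex-symmetric survival) each tagged with the
invariant it exercises.  These emulate the structure of the model's inputs,
not empirical data: rates are i.i.d. across classes with no senescence trend,
no environmental stochasticity, and no measurement noise.  Passing tests
therefore demonstrate correctness of the dynamics and transforms, not
realism of any particular life history.

## Known limitations

* No stochastic (branching-process) demography and no continuous-age PDE
  solver; the discretization is the model.
* Background (non-focal-game) fertility and mortality are not exposed; all
  vital rates flow through the focal game payoffs.
* Boundary states — empty age classes, extinct strategies, all-male or
  all-female populations — are outside the dynamics' domain and fail loudly
  rather than being regularized.
* The trajectory CSV schema stores states, not solver internals; re-reading
  a file reproduces the numeric payload exactly but not the run metadata.
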
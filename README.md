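# agerep — age-structured replicator dynamics

`agerep` is a simulator library for evolutionary game dynamics in populations
with explicit age structure.  It is aimed at theoreticians in evolutionary
ecology and life-history theory who want to couple frequency-dependent
selection (replicator dynamics) to classical demography (Leslie matrices,
stable age distributions, the Euler–Lotka equation) without writing a bespoke
ODE system by hand.

## The model

A population carries `w` strategies across `m + 1` unit age classes
(class 0 = newborns).  One round of the focal game gives a `j`-strategist of
age `i` a fertility payoff `f_j^i(p, a)` and a death probability
`d_j^i(p, a)`; with interaction rate `τ` (fraction of individuals playing per
time unit) the vital rates are `τ f_j^i` and survival `s_j^i = 1 − τ d_j^i`.
Recruitment is density-dependent through the logistic factor `(1 − n/K)`
applied to fertility only, so the turnover of generations is not suppressed
at carrying capacity.

The same dynamics can be written in two mutually equivalent coordinate
systems, both provided (with exact transforms between them):

* **strategy-major (Sa)** — strategy frequencies `p_j`, one age structure
  `a_j^i` per strategy, and size `n`:

  ```
  ȧ_j^i = a_j^{i−1} s_j^{i−1} − a_j^i ( f̄_j (1 − n/K) + s̄_j )
  ṗ_j   = p_j ( (f̄_j − f̄)(1 − n/K) + (s̄_j − s̄) )
  ṅ     = n ( f̄ (1 − n/K) + s̄ − 1 )
  ```

* **age-major (Sb)** — global age structure `a^i` and per-class strategy
  mixes `p_j^i`.

With constant rates the age dynamics are attracted to the manifold
`â^i ∝ Π_{z<i} s^z / λ^i` with `λ = r̄ + 1`, which is the stable age
distribution of the associated Leslie matrix; on it the Euler–Lotka
characteristic equation `Σ_i λ^{−(i+1)} f^i Π_{z<i} s^z = 1` holds.  The
`demography` module provides these classical quantities independently
(power-iteration eigenpairs, root-solving the characteristic equation) so the
dynamic systems can be verified against them.

The built-in case study (`sexratio` module) applies both coordinate systems
to sex-ratio evolution: a gene expressed by females encodes the fraction of
male newborns `P_j` in a brood of `k`; survival is sex- and age-specific and
each sex is reproductively active in its own window of age classes.  A gene's
excess fertility payoff reduces to the Shaw–Mohler form
`k[(S_j^f/S̄^f + S_j^m/S̄^m)/2 − 1] S̄^f`, where `S_j^f`, `S_j^m` are its
fractions of active females and males.  The headline behaviour: even with
sex-asymmetric mortality the primary sex ratio converges to 0.5, but at that
equilibrium the Shaw–Mohler term is *not* zero — it is exactly balanced by the
survival excess `s̄_j − s̄`, so the classical fertility-only Fisherian
argument does not by itself explain the outcome.

## Worked example

Run the sex-ratio case study from the command line (three strategies
P = 0.05, 0.55, 0.95; 26 age classes; female survival 0.95 then 0.80 from
class 10, male survival 0.88 then 0.72 from class 15; females fertile in
classes 8–15, males active in 8–20; n(0) = 40, K = 10 000):

```sh
$ agerep sexratio-fisher --out demo
agerep 0.1.0 sexratio-fisher (k=6.0)
final time: 821.0
primary sex ratio P_pr: 0.500000
operational sex ratio P_op: 0.388359
gene frequencies G: [0.252184 0.234164 0.513652]
population size n: 9048.320
```

The primary sex ratio (average strategy of active females) settles at 0.5
while the operational sex ratio stays far from it (0.388: active males
outnumber what a naive reading would suggest is "even"), and all three
strategies coexist.  `demo/trajectory.csv` holds the full trajectory in a
tidy schema (`time, system, variable, strategy, age_class, value`).

The same scenario is available programmatically via
`agerep.fixtures.fisher_scenario()` and as a YAML file
(`src/agerep/scenarios/sexratio_fisher.yaml`) for `agerep simulate`.

Classical demography on its own:

```python
>>> from agerep import demography
>>> rates = demography.AgeVitalRates(f=[0.0, 0.0, 4.0], s=[1.0, 1.0, 0.0])
>>> eq = demography.dominant_structure(rates)
>>> round(eq.growth_multiplier, 6)
1.587401
>>> eq.age_distribution.round(6)
array([0.493386, 0.310814, 0.1958  ])
>>> round(demography.solve_intrinsic_rate(rates, timing="end"), 6)
0.462098
```

A semelparous life history with brood size 4 at age 2 grows by
`λ = 4^{1/3} ≈ 1.5874` per time step, and the newborn-census Euler–Lotka
root is `ln λ`.

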
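# filicann

Is eating your own offspring ever a good foraging strategy?  `filicann`
models a strictly territorial, filially cannibalistic predator — the damsel
bug *Nabis pseudoferus* hunting *Spodoptera exigua* larvae — and asks whether
the cannibalism rate that is optimal for an individual female is also optimal
for her lineage.  It is a desk-scale research tool for behavioural and
population ecologists: every input is a small printed parameter set, every
result is a deterministic recursion plus a grid sweep, and everything runs in
seconds on one CPU.

## The model

Time advances in 5-day steps.  A female forages T = 4800 minutes per step
(16 h daylight per day).  Her brood develops through six cohorts: two egg
steps, three cannibalizable nymph classes (one step each), then a young adult
that leaves to found her own territory after one migration step.  While the
mother lives (L = 7 steps) she feeds on a constant supply of *y*
heterospecific prey per territory and on her own nymph cohorts, governed by a
prey-preference-dependent Holling type II functional response.  With nymph
counts c₃, c₄, c₅ (x = c₃+c₄+c₅), encounter shares s_A = x/(x+y),
s_B = y/(x+y), and preferences (P_A, P_B) — the probabilities of attacking an
encountered conspecific / heterospecific — one search-encounter cycle lasts

    C = τ_s + s_A·P_A·τ_a + s_B·P_B·τ_b

and the per-minute consumption rates are s_A·P_A·(c_i/x)·k_i / C for nymph
class i (k_i = attack success) and s_B·P_B / C for heterospecific prey.  The
brood is depleted continuously within each activity window; the
heterospecific density stays fixed.  Consumption converts to newly hatched
nymphs through the numerical response e = a₃·n₃ + a₄·n₄ + a₅·n₅ + b·n_het.

Two fitness functionals are optimized over (P_A, P_B) ∈ [0,1]² on a uniform
100-point grid:

* **X — life reproductive success**: adult daughters leaving the focal
  female's territory over her lifetime, X = Σ_τ a(τ).
* **Z — reproductive-season growth**: living descendants of the founding
  female ("Eve") after a 50-step (250-day) season, computed by a renewal
  recursion over founder counts, f(t) = Σ_τ f(t − τ − 6)·a(τ), because every
  descendant repeats her mother's schedule time-shifted.

A key mechanism: an encountered-but-ignored nymph still costs the search
time, so a non-cannibal female's growing brood crowds her encounters and
depresses her heterospecific intake.  Low-rate cannibalism can therefore pay
for the individual (X) while still losing at the lineage level (Z), through
the time-delay and lineage-elimination costs of eating descendants.

## Worked example

```
$ filicann surface --scenario real --fitness X --grid 100 --out out/
max X = 525.632 at (P_A=0.1717, P_B=1.0000)
$ filicann surface --scenario real --fitness Z --grid 100 --out out/
max Z = 2.54453e+16 at (P_A=0.0000, P_B=1.0000)
```

With the laboratory-measured parameters, life reproductive success peaks at a
*partial* cannibalism rate P_A ≈ 0.17 (eating roughly one encountered nymph
in six), while the season-end descendant count is maximized by *no*
cannibalism at all — the central qualitative result: filial cannibalism is
individually optimal foraging here, but not evolutionarily optimal.  With the
illustrative parameter set, where conspecific nymphs are made more valuable
food than the heterospecific prey, both optima are cannibalistic but the
lifetime optimum (P_A ≈ 0.67) is greedier than the season optimum
(P_A ≈ 0.31):

```
$ filicann compare --scenario illustrative --grid 100 --out out/
{ "argmax_X": {"p_a": 0.6667, "p_b": 1.0}, "max_X": 45.3047,
  "argmax_Z": {"p_a": 0.3131, "p_b": 1.0}, "max_Z": 5.2023e+06 }
```

The same operations are available as library calls
(`filicann.fitness_surface`, `filicann.run_focal_female`,
`filicann.season_growth`, …), and `filicann oracle` cross-checks the
deterministic recursion against an individual-based Monte-Carlo simulation.

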
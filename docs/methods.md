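# Methods

## Model overview

`filicann` implements a deterministic, discrete-time cohort model of one
territorial predatory female and, by extension, of her whole lineage over a
reproductive season.  The state is real-valued (expected counts): the
recursion multiplies by attack and success probabilities, so integer
bookkeeping would be wrong for the mean dynamics.  There is no mortality
other than maternal cannibalism, no sex structure (all offspring are treated
as daughters; males are assumed non-limiting), no migration loss, and no
temperature dependence — development runs on physical time.

### Time axis and life history

| quantity | default | meaning |
|---|---|---|
| `unit_days` | 5 d | one step |
| `activity_minutes_per_unit` | 4800 min | foraging time per step (16 h/day) |
| `egg_units` | 2 | steps from laying to hatch |
| `nymph_stage_units` | 1 | steps per cannibalizable nymph class (×3 classes) |
| `maternal_reproductive_units` (L) | 7 | steps the mother lays and forages, then dies |
| `migration_units` | 1 | steps between leaving the natal territory and founding |
| `season_units` (S) | 50 | reproductive season (250 d) |

A cohort laid at maternal age τ is: egg at steps τ and τ+1; nymph class 1/2/3
(cohorts 3–5, success probabilities k₃/k₄/k₅) at τ+2/τ+3/τ+4; and departs as
a young adult during step τ+5.  She founds her own territory at step τ+6 of
the natal calendar and starts the identical schedule there.  Within a step
the event order is forage → remove consumed nymphs → lay → advance, which
puts the first cannibalizable stage two rows after its laying age in the
schedule table, as in the descendants scheme this model follows.

### Functional and numerical response

Encounters are abundance-weighted: after a search of τ_s minutes the female
meets one item — a class-i nymph with probability s_A·w_i (s_A = x/(x+y),
w_i = c_i/x) or a heterospecific prey with probability s_B = y/(x+y).  She
attacks with probability P_A (conspecific) or P_B (heterospecific); an attack
costs the full handling time (τ_a or τ_b) whether or not it succeeds, and a
conspecific attack kills with probability k_i.  The expected cycle time is
C = τ_s + s_A·P_A·τ_a + s_B·P_B·τ_b, giving instantaneous consumption rates

    r_i   = s_A · P_A · w_i · k_i / C        (nymph class i)
    r_het = s_B · P_B / C                    (heterospecific prey)

Three design choices deserve emphasis:

1. **Ignored encounters still cost search time.**  The preference is the
   probability of attack *upon encounter*; a female that never attacks her
   own nymphs still stumbles over them.  As the brood accumulates it crowds
   the encounter stream and depresses heterospecific intake.  This
   time-budget interference is what makes low-rate cannibalism individually
   profitable with the measured parameters.
2. **Failed attacks pay handling.**  Subduing attempts on large nymphs cost
   time even when the nymph escapes (1 − k_i).  The alternative (charging
   handling only on success) shifts the lifetime-success optimum off the
   measured-parameter grid point and was rejected during calibration.
3. **Within-step depletion.**  The brood is finite, so the rates above are
   integrated over the 4800-minute window as an ODE (the encounter shares
   re-equilibrate continuously as nymph classes thin out); heterospecific
   density is constant throughout (the territory is open to renewal of
   heterospecific prey, and depletion of it is outside scope).  A classical
   fixed-density disc-equation evaluation is exposed separately
   (`functional_response`) and is the form verified against the stochastic
   renewal oracle.

The numerical response is linear: e = a₃n₃ + a₄n₄ + a₅n₅ + b·n_het new
hatched-nymph equivalents per step, laid as eggs the same step.  The
coefficients already fold in egg-to-nymph hatching success, which is why the
model never tracks laid-but-inviable eggs separately.

### Fitness definitions

**X (life reproductive success)** is the total number of adult daughters
that leave the focal female's territory, X = Σ_τ a(τ).  Counting hatched
nymphs Σe(τ) instead was considered and rejected: it disagrees with the
published optima in both location and magnitude.

**Z (season growth)** counts the living descendants of the founder Eve at
the end of step S.  Because all females share the phenotype and environment,
each founder repeats the same schedule time-shifted and founder counts obey
the renewal recursion f(t) = Σ_τ f(t − τ − d)·a(τ), d = 6, f(1) = 1.  The
census at the season's end counts, per territory: the post-cannibalism nymph
cohorts, the daughters in their departure step, and the founding female
while she lives (her first L steps); Eve herself is excluded.  Two
conventions were calibrated against the published illustrative-set value of
Z (a hyper-sensitive quantity, see Limitations) and fixed:

* **Unhatched egg cohorts are not counted.**  Z counts hatched individuals;
  including the two standing egg cohorts multiplies Z by ~3 and moves the
  illustrative optimum off its published grid point.
* **The settling step is not censused.**  A daughter is counted in the step
  she departs; between departure and her first step as a territory owner
  (one step later) she does not appear in any census slot.

An explicit generation-by-generation expansion of the descendants tree
(`descendants_tree_census`) is kept as an independent cross-check; renewal
and tree agree to 1e-9 relative across random parameter sets.

### Optimization

Both surfaces are swept exhaustively on the uniform grid {i/(n−1)}², default
n = 100 — the published optima are exact multiples of 1/99 (17/99, 66/99,
32/99, 97/99), which identifies that grid.  Surfaces here are non-concave
(crowding relief versus lineage elimination), so no gradient method is used;
the full sweep costs ~2 s.  Ties break toward the smallest P_A, then the
smallest P_B, so a degenerate all-zero surface reports the origin.

## Numerical choices

* Within-step depletion uses fixed-step RK4 with 150 sub-steps per window;
  maxima change by <1e-4 relative when doubled.  Nymph states are clamped at
  zero after each sub-step; consumption rates treat negative inputs as zero.
* Empty territory (x + y = 0) or zero time yields exactly zero consumption.
* The vectorized grid engine and the scalar single-point path share one code
  path; the optimizer's reported maximum is verified (in tests) to equal a
  scalar re-evaluation at the reported argmax.
* All cohort/consumption arrays are indexed by maternal age τ starting at 1
  (index 0 unused) to keep the code aligned with the schedule notation.

## Synthetic scenarios and oracles

`random_parameters(seed)` draws structurally valid sets: y ∈ [1, 50],
b ∈ [0.01, 2], times ∈ [1, 120] min, k_i ∈ [0.1, 1] sorted non-increasing
(bigger nymphs escape more), a_i ∈ [0.1, 15] sorted non-decreasing (bigger
nymphs carry more biomass) — the orderings of the measured set.  These
emulate the *structure* of laboratory-estimable parameters, not any field
population; passing property tests on them demonstrates internal
consistency, not realism of any particular draw.

Two independent stochastic oracles validate the deterministic arithmetic:

* a **renewal-bout simulator** (fixed densities, sequential search/attack/
  handling with Bernoulli outcomes) whose mean consumption is compared with
  the disc-equation form within 3 standard errors plus a one-item truncation
  allowance (a bout ends mid-cycle; the deterministic form does not);
* an **individual-based territory simulator** with integer nymphs, within-
  bout depletion and Poisson offspring whose mean e(τ), a(τ) — and, for tiny
  configurations, Z — are compared with the recursion within 3 SE.

The territory comparison is run in a deliberately weak-crowding regime
(heterospecific density 150–400, short 600-minute windows, long searches):
there one female's consumption barely perturbs the encounter shares, the
mean-field recursion is the exact expectation up to O(1/N), and a 3-SE test
is meaningful.  In strongly nonlinear regimes the recursion is a mean-field
approximation and the individual-based mean deviates systematically
(Jensen-type bias), which is a property of mean-field modelling, not an
implementation error.

## Known limitations

* **Season-end descendant counts are hyper-sensitive.**  Z compounds the
  per-step lineage growth factor over 50 steps: a 1% difference in that
  factor changes Z by ~65%, a 3% difference by ~5×.  The package reproduces
  the published optimum *locations* for Z exactly (no cannibalism with the
  measured parameters) and the illustrative-set Z magnitude to ~4% at the
  grid optimum, but the measured-set Z magnitude comes out ~5× below the
  published figure; with the published formula details unavailable, the
  reconstruction documented above is the best-calibrated form and the
  discrepancy should be read with the compounding sensitivity in mind.  X
  maxima reproduce to better than 1%.
* The heterospecific supply never depletes, territories never interact, and
  there is no density dependence between lineages.
* Development is temperature-independent and the season boundary is sharp;
  overwintering survival is out of scope.
* The lifespan L is diet-independent (measured oviposition spans differ
  between conspecific- and heterospecific-fed females; the model uses the
  7-step schedule throughout).
* The individual-based oracle is a test instrument, not a research-grade
  IBM; it is pure Python and intended for small replicate counts.
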
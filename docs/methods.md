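# Methods

## The model

`mmcds` simulates somatic evolution in a single well-mixed, self-renewing
stem-cell compartment — the setting is human hematopoietic stem cells, but
nothing in the engine is tissue-specific. The state is an explicit list of
cells, each carrying two numbers: its count of driver mutations and the time
since its last division. The simulation advances in weekly updates over a
default lifespan of 5,200 weeks (100 years). Each week, every cell passes
through three stages:

1. **Division.** The cell's time since last division is compared with a
   threshold drawn fresh from Normal(μ, μ/8), where μ is the mean division
   interval at the current age; negative draws are truncated at zero. If the
   timer has reached the threshold, the cell is replaced by two daughters
   with timers reset to zero; otherwise the timer advances one week.
2. **Mutation.** Each new daughter independently acquires one driver with
   probability equal to the *phenotypic mutation rate* (default 1e-3 per
   division) — the probability of any heritable genetic or epigenetic change
   that alters somatic fitness, hence much higher than a per-base-pair
   mutation rate. At most one driver is gained per daughter per division.
3. **Competition.** Every cell survives an independent binomial trial with
   probability min(1, (K/N)·f_i/f̄): K is the pool capacity at the current
   age, N the post-division cell count, f_i = (1+s)^k the somatic fitness of
   a cell with k drivers at the current selection coefficient s, and f̄ the
   pool's mean fitness. The text sources for this architecture state the
   three dependencies (capacity, competitor count, relative fitness) but not
   the functional form; this multiplicative form is our interpretation. It
   keeps the expected pool size at K under neutrality and makes survival
   odds linear in relative fitness.

Driver fitness effects compose multiplicatively, (1+s)^k, so multiple
drivers are synergistic rather than additive. Under the **MMC** selection
model s is a constant (default +0.5% per driver). Under **MMC-DS** s is a
function of age: a plateau of −neg_max early in life rising to +pos_max late
in life, crossing zero at a configurable switch age — somatic selection that
mirrors physiological aging. MMC-DS fitness is re-evaluated every week from
the current age's coefficient applied to all accumulated drivers; a driver's
effect is dynamic, not fixed at its time of occurrence.

Reported output per run is the weekly pool size and the sizes of the nested
clone classes carrying ≥1, ≥2, ≥3 and ≥4 drivers (a cell with 3 drivers
counts toward the first three classes). Driver counts themselves are
unbounded.

## Age-dependent schedules

Three deterministic curves of simulated age (weeks, 52 per year) drive the
engine:

- **Pool capacity**: 300 cells at birth growing sigmoidally to 10,000 by
  maturity (default 988 weeks = 19 years, the midpoint of the 18–20-year
  range the growth estimates support), then constant. With
  `proportional_start` (default on) the starting pool scales with the adult
  pool, preserving the 300:10,000 ratio; the pool-size sweep scenario turns
  it off so every condition starts from 300 cells.
- **Division interval**: either *stable* (one division per ~20 weeks for
  life — the classical constant-rate assumption) or *dynamic* (one per ~3
  weeks at birth slowing to one per ~40 weeks by maturity; the adult
  interval is sweepable to 70 weeks).
- **Selection coefficient**: constant (MMC) or the rising logistic described
  above (MMC-DS).

No analytic form for these curves is published — only their plotted shapes
and anchor values — so all three use logistic interpolation between the two
plateaus. Growth and division curves are renormalized so the anchors are
met *exactly* at week 0 and at maturity (and clamped constant afterwards).
The selection curve is a pure logistic: its center is placed analytically
(t0 = switch − w·logit(neg/(neg+pos))) so the zero crossing sits exactly at
the switch age and shifting the switch age translates the whole curve
rigidly. Its plateaus are therefore asymptotic rather than exact, with
residual < 1e-9 at the default transition width of 150 weeks and switch age
of 50 years. These two requirements — exact plateaus and exact translation
equivariance — cannot both be satisfied by one clamped form, and for the
selection curve the crossing and the shift family are the scientifically
meaningful properties.

## Numerical implementation

The production path is a numba-compiled kernel fusing the three weekly
stages. Two exact, distribution-preserving rewrites make it fast:

- Drawing a Normal threshold and comparing is replaced by a Bernoulli trial
  with p = Φ((timer − μ)/(μ/8)), tabulated per week over integer timer
  values (every cell that has divided at least once has an integer timer;
  founder cells with fractional initial timers are evaluated directly).
- Per-cell Bernoulli trials with a shared probability (cells in the same
  timer bucket, or the same driver-count class during competition) are
  sampled as one Binomial count plus a uniformly chosen subset (partial
  Fisher–Yates) — exchangeability makes this identical in distribution to
  independent per-cell draws.

The public operations `attempt_divisions`, `apply_mutations`, `compete` and
`step` are plain numpy and define the reference semantics; `run_simulation`
accepts `backend="numpy"` to run the composed reference operations, and the
test suite checks the two paths agree statistically. The kernel and the
numpy backend consume different random streams, so they are compared in
distribution, not bitwise.

Determinism: a run is bit-identical given (config, seed, backend).
Replicate seeds are derived from the base seed with numpy's `SeedSequence`,
so replicates are individually reproducible and results are independent of
the worker count used to run them. Sweep levels run from the same base
seed, giving matched per-replicate seeds across conditions.

Degenerate cases: an empty pool after competition terminates the run with
an explicit extinction flag (the series is truncated, never padded); under
the default capacities extinction is effectively unreachable. Division
thresholds are truncated at zero (the negative-tail probability at sd = μ/8
is ~1e-15). The cell buffer is sized at twice the maximum capacity plus a
fluctuation margin, and overflows raise rather than silently truncate.

Initial timers are drawn uniformly on [0, interval(0)) to avoid a
synchronized division wave at startup; the source text is silent on this.
Pool statistics are recorded after competition each week. Both daughters of
a division are independently eligible for mutation.

## Replicate comparison statistics

Conditions are compared pointwise: at each week the clone-class counts of
two or more conditions (each a sample of independent runs) enter a
Kruskal–Wallis test (average ranks, standard tie correction, chi-square
approximation with df = groups − 1). Weeks where every run in every group
holds the identical value have zero rank variance; they are reported as
p = 1, read as "identical behavior". The p-value curve is summarized by its
normalized area — the mean p-value, equivalently the area under the curve
divided by the 1 × T chart area. No correction is applied across the 5,200
weekly tests: the area ratio is a descriptive magnitude of overall
difference (1 = indistinguishable, → 0 = different almost everywhere), not
a familywise inference.

Two run-level summaries support the figure-style analyses: the *takeover
week* (first week a clone class exceeds a stated fraction, default 50%, of
the current pool) and the *early transient* detector (a clone-class peak of
at least 2 cells before age 10 followed by a ≥50% decline from that peak by
age 30).

The incidence-normalization utility divides a user-supplied non-negative
series by its maximum, mapping the peak to exactly 1 while preserving
shape; it touches no simulation state.

## Standard parameter set (reconstructed)

The original supplementary parameter tables are not distributed with this
package. The baseline used by the scenario registry is reconstructed as the
midpoint of each published sweep and is clearly overridable: adult pool
10,000; dynamic division 3→40 weeks; mutation rate 1e-3; MMC advantage
+0.5% per driver; MMC-DS ±0.5% with switch at 50 years; 50 replicates.
Under this baseline expansions run earlier than in the published charts
(whose exact parameter set is unknown); all qualitative contrasts — sweep
orderings, the MMC-DS delay, pool-size invariance, the childhood transient —
are insensitive to this choice.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen for a desktop-scale single-CPU budget:

- Sweep fixtures in the test suite: 50 replicates per level at full size
  (5,200 weeks, 10,000-cell pool) for the division-profile, mutation-rate,
  fitness-advantage and switch-age sweeps; 8 replicates per level for the
  pool-size sweep (whose largest level costs 10× per run).
- The early-transient comparison runs 1,000 individual runs per model at a
  reduced adult pool of 2,500 cells and a 1,560-week horizon: the statistic
  only involves ages 0–30, and the drift-dominated early phase it probes
  depends on the small early pool, not on the adult plateau. The published
  analogue used 25,000 full-lifespan runs; the scenario registry defaults
  to 1,000 and is configurable upward.
- `scripts/acceptance.py` re-measures the same quantities at 12 replicates
  per sweep level (6 for the pool sweep, 400 transient runs per model).

Medians of takeover weeks across ≥12 replicates are stable to well within
the between-level separations being asserted (hundreds of weeks).

## What the simulations do and do not show

The generator *is* the study system: all conclusions are about this model
of a well-mixed, capacity-limited compartment. Real hematopoiesis has
spatially structured niches, heterogeneous and variably sized driver
effects, passenger mutations, and an incidence (transformation) process
converting clonal burden to cancer risk — none of which are simulated, so
passing tests validate the model's internal claims, not clinical
predictions. The early-transient analysis in particular demonstrates a
drift-plus-purifying-selection mechanism compatible with childhood
leukemia incidence; it does not model incidence itself.
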
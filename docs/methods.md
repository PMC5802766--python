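# Methods

`matesim` is an individual-based model of the evolution of male mating
strategies. A fixed population of females and a renewing population of
males interact on a rectangular grid of integer patches over repeated
breeding seasons; a heritable binary trait (1 = monogamous, 0 =
polygamous) determines male behavior, and its frequency is tracked as
selection, drift and mutation act across male generations. The
experimental question is how female dispersion, the adult sex ratio
(ASR), season length and mate-guarding efficiency shape which strategy
spreads.

## The world

Females never move. The `number_of_females` females occupy a regular
lattice with nearest-neighbour spacing `female_radius` patches, the
most-square rows×cols factorization of the count (20 females → 5×4).
The world measures (cols·radius)×(rows·radius) patches, so each female
sits at the center of her own radius×radius territory and the spacing
parameter *is* the female-dispersion treatment. The boundary is
non-wrapping by default; dispersion distances are then unambiguous and
edge territories are slightly favored by the random male dispersal. A
`wrap` flag turns on toroidal topology for sensitivity checks.

Males are re-dispersed uniformly at random at the start of every
breeding season, which also dissolves all pair bonds. Distances are
Chebyshev: a male moves to one of its ≤8 neighbouring patches per tick,
so "one patch per tick" equals one distance unit per tick. "Move
toward" picks uniformly among the neighbouring patches that minimize
the Chebyshev distance to the target; "random move" picks uniformly
among the in-bounds neighbours.

## The behavioral rules

Each tick: every positive female refractory counter is decremented,
then every male acts once, in a freshly shuffled order (emulating
randomized agent scheduling; at most one copulation per female per
tick).

A female is *available* to a candidate male if she is not pregnant,
not refractory, not guarded by another male, and no *free* male — one
who is neither paired nor already engaged to a target — is strictly
closer to her (ties do not block). Searching males — polygamous males
and monogamous males that have not yet paired — acquire the nearest
available female as their target (ties to the lowest female id) and
are then *engaged*: they pursue her tick by tick until she becomes
pregnant or guarded, without re-evaluating the field. Availability is
checked only at acquisition. The free-male clause makes suitors fan
out across females where that is possible, while an engaged or paired
male stops blocking, so a latecomer may join a pursuit rather than
drift; whoever reaches the female's patch first copulates. If an
engaged male's target turns refractory (a rival arrived first), he
holds a loose position — random one-patch moves near her, not glued to
her patch — and closes back in the moment she is receptive. A male
with no available female random-walks.

After a copulation the polygamous male abandons the target and
re-searches from scratch; his late partner is refractory, so he
necessarily turns to other females — the stated role of the refractory
period — or, when none is in reach, wanders until one frees up.

A copulation makes the female pregnant with probability
`pregnancy_chance` (default 0.05) — pregnancy lasts to season end and
records the father's genotype — otherwise she becomes refractory for
`refractory_period_duration` full ticks. Internally the counter is
stored as duration+1 because it is first decremented on the following
tick; the observable rule is that a female is unavailable for exactly
`refractory_period_duration` ticks after the copulation tick, so a
guarded pair copulates every `refractory_period_duration + 1` ticks and
the number of copulation opportunities in a season of T ticks starting
at t₀ is N = ⌊(T−1−t₀)/(r+1)⌋+1. This closed form is asserted against
simulation in the tests.

A monogamous male pair-bonds to the first female he copulates with,
whatever the outcome. With `mate_guarding` on he then stays on her
patch for the rest of the season, copulating whenever her refractory
ends; the guard makes her unavailable to every other male (the
strict-closer clause already blocks any male at positive distance; the
explicit guard rule also covers the degenerate case of an intruder
random-walking onto her patch). With `mate_guarding` off he wanders in
an unbiased random walk while she is refractory or pregnant and heads
back to copulate when she is receptive — leaving her exposed to other
males in the meantime (extra-pair copulation). He never courts other
females; this is the narrowest reading of "not fully efficient
guarding" and is isolated in one branch of the male-step rule should a
different wandering rule be wanted.

## Genetics and the life cycle

At season end each pregnant female contributes one progeny genotype to
a trait pool: the father's genotype perturbed by Gaussian noise and
threshold-rounded,

    G1 = round(G0 + N(0, sigma)),   round(x) = 1 iff x >= 0.5,

with sigma = 0.35 by default, giving a symmetric flip probability
1 − Φ(0.5/0.35) ≈ 0.0766 that keeps the population off the absorbing
monomorphic states without drowning selection. Mutation is applied once,
at contribution time; turnover sampling adds no further noise.

All males die together every `longevity` seasons (default 4) and are
replaced by genotypes drawn uniformly *with replacement* from the pool,
keeping the male count — and hence the ASR — constant; the pool is then
cleared. The pool may hold more progeny than there are male slots; not
every pregnancy yields a male, so the population lags the pool
distribution. If a whole generation produced no pregnancy the dying
generation's genotype multiset carries over unchanged (no selection
occurred); this degenerate case is logged in the trajectory, not an
error. The founding generation is an independent fair coin per male.
Females have no genetics and are never replaced.

A debug `neutral_mode` makes both genotypes behave polygamously
(no pairing, no guarding), so the trait is selectively neutral; the
test suite uses it to verify that drift plus symmetric mutation keeps
the long-run mean monogamous fraction at 1/2.

## Outcome and experiments

The primary outcome of a run is **percentage monogamy**: the percentage
of breeding seasons in which *strictly* more than half the males
carried the monogamous genotype. The sweep harness crosses

    number_of_males            15, 20, 25   (ASR 43%, 50%, 56%)
    female_radius              5 … 35 by 5
    season_duration            200, 400, 600, 800 ticks
    refractory_period_duration 10, 30
    mate_guarding              on, off

(336 cells), runs each cell with replicate seeds derived via
`SeedSequence(base_seed, cell_index, replicate)`, and summarizes cells
as replicate means with Student-t 95% confidence intervals.

The sensitivity analysis min-max normalizes female radius, season
duration, number of males, an extra-pair dummy (1 = guarding off) and
the response to [0, 1] and fits OLS. The fit includes an intercept —
omitting it would inflate R² artifactually since the response is not
centered; a `--no-intercept`/`intercept=False` option exists for
comparison. Two companion analyses mirror the in-text results: the same
model and four single-predictor models on the refractory = 10 subset,
and a simple regression of monogamy on female radius inside the
15-males/200-tick/guarding-on slice, where dispersion is the dominant
predictor.

## Numerical and performance choices

The per-tick rules are compiled with numba and shared verbatim between
the step-level API (`World`, `step_male`, `run_season`) and the
whole-run driver (`run_simulation`): both consume one
`np.random.Generator` in the same draw order, and a test asserts the
two paths produce bit-identical trajectories. Engagement makes the hot
loop cheap: target selection (an O(males x females) scan) runs only on
re-engagement events, engaged males step in O(1), and once every
female is pregnant the remainder of the season short-circuits to the
random-walk moves the full rules would produce anyway, drawing from
the RNG identically so trajectories stay bit-reproducible. A
randomized property test asserts the kernel's availability and
selection agree with a plain-Python restatement of the rule. Runs are
embarrassingly parallel in principle but executed serially; seeds are
derived per (cell, replicate), so results are independent of execution
order.

Reported experiment sizes: the full-grid analyses in the tests and the
acceptance script use 30 generations and 3 replicates per cell (the
original study used 150 and 5); the dispersion-slice fit keeps the
full 150 generations with 5 replicates, since it is 35 runs rather
than a thousand. At 30 generations the early transient (founding
frequencies near 1/2) carries more weight than at 150, which mostly
attenuates extreme cell means and the fitted R² values; the regression
structure is robust to this.

## What the synthetic conditions do and do not show

All inputs are generated by the model itself; there is no field data
anywhere. The generator realizes exactly the study conditions above:
perfectly regular female spacing, identical females, uniform male
dispersal, sharp season boundaries, synchronized male death and a
constant ASR. Real populations violate all of these — territory sizes
vary, females move and choose, generations overlap, ASR fluctuates.
Passing tests therefore validate the *mechanism* (how dispersion, sex
ratio, season length and guarding interact to select for monogamy
under these idealizations), not any quantitative claim about a real
species.

## Known limitations

- Continuous space, female mate choice, female movement, infanticide,
  parental care and non-breeding periods are out of scope by design.
- The courtship micro-rules — who may block whom at target
  acquisition, how committed an engaged male is, and what a suitor
  does while his target is refractory — are underdetermined by verbal
  model descriptions, and the population-level sensitivity pattern is
  quite responsive to them. The variants were explored systematically
  (strict per-tick nearest-male exclusion; unconditional convergence;
  camping on a refractory target; leaving at refractory) and the
  implemented combination is the one whose regimes jointly match the
  documented qualitative behavior; the quantitative sensitivity
  ordering still differs (dispersion stronger, sex ratio weaker, than
  the reference analysis reports), which should be kept in mind when
  comparing absolute coefficient values.
- The wandering rule of a non-guarding paired male is likewise a
  choice among defensible readings and measurably affects how much
  extra-pair copulation occurs.
- Chebyshev geometry makes diagonal moves as cheap as axial ones;
  Euclidean or hex geometries would change effective dispersion
  distances by up to √2.
- With `longevity` low, selection responds slowly because the pool is
  resampled only at generation turnover; the default 4 matches the
  reference conditions.
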
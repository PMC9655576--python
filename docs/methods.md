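# Methods

## The model

`trophallaxis` simulates the redistribution of liquid food inside a colony of
social-insect workers (the reference system is a queenless, broodless group of
~53 *Lasius niger* workers with unlimited access to a sucrose source).  Time
advances in 1-second steps; every behavioural decision is a Bernoulli draw
whose probability is modulated sigmoidally by the ant's current crop load
`Q_i` through a Hill term with half-saturation `k` and steepness `n`:

| decision                | probability per step                  | shape          |
|-------------------------|---------------------------------------|----------------|
| donate food             | `theta_i(0) * Q^n / (k^n + Q^n)`      | rises with Q   |
| receive food            | `gamma_i(0) * k^n / (k^n + Q^n)`      | falls with Q   |
| leave the nest to feed  | `alpha_i(0) * k^n / (k^n + Q^n)`      | falls with Q   |

Defaults `n = 2`, `k = 120` food units.  `k` is a single global threshold by
default; the response functions and per-ant trait records accept individual
thresholds (array-valued `k`), but the colony simulator applies the global
value — individuals plausibly differ in their thresholds, yet one shared `k`
suffices for the fitted behaviour.

A colony starts with every worker in the nest, non-forager (NF), crop empty.
Each step applies four phases in a fixed, documented order (a config flag
swaps phases 2 and 4 for sensitivity checks):

1. **Transfers** — each engaged pair moves `transfer_rate` units from donor to
   receiver, truncated if the donor empties (which ends the event); the pair
   then separates with probability `phi`.  A newly formed pair performs its
   first transfer (and separation draw) in the formation step, so a
   single-step event moves exactly one transfer quantum and event durations
   are geometric with mean `1/phi`.
2. **Departures** — each unpaired nest ant leaves for the source with
   probability `alpha(Q)`.  A first departure makes the ant a forager (F),
   permanently: its leaving maximum becomes `alpha'(0) =
   forager_multiplier * alpha(0)` (capped at 1), and under the
   two-emergent-caste regime its `theta(0)`/`gamma(0)` are resampled from the
   forager distributions, uncorrelated with the pre-visit values.
3. **Source** — each feeding ant ingests `intake_rate` units and starts home
   with probability `beta` (optionally via a fixed `return_delay` transit).
4. **Encounters** — each unpaired nest ant, in random order, draws one
   uniformly random unpaired nest partner `j`.  The encounter starts an
   exchange `i -> j` with probability `theta_i(Q_i) * gamma_j(Q_j)`, failing
   that `j -> i` with probability `theta_j(Q_j) * gamma_i(Q_i)`.

The encounter rule deserves a note: every nest ant can engage **either as
donor or as receiver**, with the pair forming at the product of the two
individual probabilities.  A donor-only variant (the initiating ant can only
give) was evaluated during development and cannot reach the observed colony
activity level (~99 events/hour) under the reference giving/receiving means —
encounters initiated by empty ants are all wasted — so the bidirectional rule
is the package's model.  Food is conserved exactly: with integer-valued
`intake_rate`/`transfer_rate` all crop arithmetic is exact in double
precision, and the per-step assertion `sum(crop) == total_withdrawn` is
enforced in validated runs.

## Heterogeneity and castes

Giving/receiving maxima are drawn per ant from one of three families with a
common mean `eps` and increasing spread: **delta** (everyone identical),
**uniform** on `[0, 2*eps]` (the widest nonnegative uniform with that mean;
an exactly mean-matching uniform with SD equal to the mean does not exist on
a nonnegative support, its SD is `eps/sqrt(3)`), and **exponential** with
mean `eps`, resampled into `(0, 1]` so draws remain probabilities (rejection,
not clipping, to avoid an atom at 1).  The exponential density is
parameterized by its *mean* — so the fitted per-caste values (e.g. 1/9) are
population means on the probability scale in all three families.

Under the one-caste (OC) regime traits never change.  Under the
two-emergent-caste (TEC) regime, promotion resamples from the forager
distributions.  The validator enforces the defining division-of-labour
direction, `mean(theta_F) > mean(theta_NF)`; the receiving direction is left
free because the fitted reference values place `gamma_F` *above* `gamma_NF`
(foragers, usually empty when in the nest, are strong receivers) even though
a qualitative statement of the two-caste hypothesis might suggest the
opposite.

The fitted per-caste means shipped as presets (`trophallaxis.TRAIT_MEANS`):

| regime, distribution | theta_F | theta_NF | gamma_F | gamma_NF |
|----------------------|---------|----------|---------|----------|
| OC delta             | 1/11    | = F      | 1/60    | = F      |
| OC uniform           | 1/10    | = F      | 1/50    | = F      |
| OC exponential       | 1/6     | = F      | 1/56    | = F      |
| TEC delta            | 1/10    | 1/33     | 1/11    | 1/38     |
| TEC uniform          | 1/11    | 1/32     | 1/9     | 1/28     |
| TEC exponential      | 1/9     | 1/23     | 1/9     | 1/27     |

Nest-leaving maxima `alpha_i(0)` follow a bounded power law (Pareto,
survival `~ x^(1-a)` on `[m, M]`): a few ants are very likely to visit the
source, most almost never do, which matches the survival curve of first
arrivals at a food source after starvation.

## Calibrated rate defaults

The remaining rates are not identifiable from published tables and were
calibrated, once, by grid search against the reference ensemble statistics
(53 ants, 3600 steps: mean trophallactic events ≈ 98.7–101 per variant, mean
foragers ≈ 12.2–12.6, non-forager share of donated volume ≈ 40%):

| parameter            | default  | meaning                                      |
|----------------------|----------|----------------------------------------------|
| `beta`               | 0.02     | leave the source (mean feeding bout 50 s)    |
| `phi`                | 1/90     | pair separation (mean event 90 s)            |
| `intake_rate`        | 10       | units ingested per second at the source      |
| `transfer_rate`      | 6        | units moved per second during an event       |
| `alpha` exponent `a` | 1.2      | heaviness of the leaving-probability tail    |
| `alpha` bounds       | 1.05e-6 … 0.02 | support of `alpha_i(0)`                |
| `forager_multiplier` | 10       | `alpha'(0) / alpha(0)` after the first trip  |

Notes on these choices:

* The lower Pareto bound `m` sets the expected forager count; `m` solving
  `E[1 - (1-alpha)^3600] = 12.4/53` analytically, then nudged upward to
  offset the crop-feedback suppression of departures, gives ~12.2–12.9
  foragers across variants.
* The tail exponent 1.2 front-loads first arrivals, which is what lets food
  circulate long enough for non-foragers to re-donate ~35% of the exchanged
  volume; steeper tails (a = 2) delay food entry and depress both the event
  count and the non-forager share.
* With donor-empty truncation the realized mean amount per event is larger
  than `transfer_rate / phi` would suggest; at the defaults it is ~240 units
  (about `2k`).  Setting `transfer_rate = k * phi` (so the untruncated mean
  is `k`) underproduces both exchanged volume and the non-forager share, so
  the defaults favour the ensemble counts over the mean-amount heuristic.
* The non-forager donated-volume share saturates near 35–36% in this model
  at every rate setting that also reproduces the event/forager means; the
  package reports what it computes.

Determinism: one `numpy` PCG64 generator per simulation, seeded; ensemble
replicate `r` uses `base_seed + r`.  The encounter phase uses an exact
thinning (pre-drawn acceptance uniforms, candidates bounded by
`theta_i * max(gamma) + gamma_i * max(theta)`) that changes the random-number
stream but not the distribution of outcomes, since crops of ants still in
the pairing pool cannot change within the phase.

## Observation model and synthetic experiments

Behavioural recordings are emulated by scan sampling: scans at
`t = 60, 120, …`; an ongoing exchange is seen at a scan iff its total
duration exceeds 5 s ("longer than 5 s" read strictly; configurable), and
consecutive scans of one raw event merge into a single observed event whose
duration is the scan count.  Merging never fuses two distinct raw events —
observation maps raw events one-to-one onto a subset — which differs from a
real observer who cannot distinguish back-to-back events of the same ordered
pair; at the default rates such collisions are rare.  Ordered pairs are kept
distinct (the same two ants with reversed roles are different events, since
flow cannot reverse within an event).

The synthetic-experiment generator runs one seeded simulation per colony
(default: 5 colonies of 53 workers, the TEC-exponential variant) through the
scan sampler and writes the tagged-colony format: per-colony scan records
(`colony, minute, donor, receiver`) and a worker table with a forager flag
assigned by the ">= 5 consecutive seconds feeding" rule (tracked as the
longest consecutive source stay).  What the generator does *not* emulate:
spatial positions (no X/Y; such columns are ignored on read), observer
identification errors, bidirectional flow within a contact, and queen/brood
effects.  Tests passing on these fixtures therefore validate the pipeline's
bookkeeping and statistics, not the biology of real recordings.

## Metrics

The exchange network is directed (donor -> receiver) and weighted by event
count, with the full roster as nodes (inactive ants stay as isolates and
contribute zeros).  Distances are unweighted hop counts; global efficiency
(mean inverse distance over ordered pairs, disconnected pairs contributing 0)
and clustering are computed on the undirected projection, betweenness on the
directed graph, closeness with the reachable-component normalization — each
switchable by flag, since the directedness convention per metric is a
reporting choice.  The Lorenz curve of per-ant event counts uses ascending
cumulative shares and the Gini coefficient is `1 - 2 * (trapezoid area)`,
giving exactly 0 for equal counts and `1 - 1/N` for a single active ant (no
small-sample correction).  `T50` is the earliest timestep by which half of
all event starts occurred.  Degenerate inputs (all-zero counts, empty logs,
single-node graphs) raise rather than return conventions.

## Calibration and comparison protocols

`summarize` reduces a run to the statistics used for fitting and comparison:
event count, forager count, pair-type counts/proportions (donor/receiver
caste resolved *at the event's start*), the non-forager donated-volume share,
Gini, T50 and efficiency.  The pair-type discrepancy `D` is the summed
absolute difference of the four counts.

`calibrate` fits selected giving/receiving means by an iteratively refined
coordinate grid search (geometric grids, shrinking spans) minimizing
`w1*|d(events)| + w2*|d(foragers)| + w3*D`, with common random numbers across
evaluations so that loss differences reflect parameters rather than
replicate noise.  It returns the best point, the full loss-surface trace and
a status flag when the evaluation budget is exhausted.

Ensemble-vs-experiment comparisons: two-sample Kolmogorov–Smirnov and
Mann–Whitney U (scipy implementations), and a resampled Z-test that mirrors a
5-colony experiment: 200 means of 5 replicates drawn without replacement
within a draw (with replacement across draws), `Z = (experimental mean -
mean of draw means) / SD(draw means)`, two-sided normal p.  A degenerate
ensemble raises.  p-values are reported at the conventional 0.05 level and
never gate pipeline flow.

## Problem sizes in the shipped checks

The packaged test-suite and the acceptance script run 100–200 replicate
ensembles of the full 53-ant, 3600-step colony (ensemble SEM of the event
count ≈ 1.2–1.9, comfortably inside the comparison bands) and a
two-parameter calibration recovery at 200-replicate evaluations; these sizes
were chosen as the smallest at which the sampling error is negligible
relative to the tolerances being checked.

## Known limitations

* No spatial structure: encounters are uniformly random among nest ants, so
  spatial segregation of castes and local mixing effects are absent.
* Unidirectional flow within an event; real trophallaxis can be
  bidirectional.
* No queen, brood, food consumption or metabolism; the source is unlimited.
* The non-forager donated-volume share plateaus ~4–5 percentage points below
  the ~40% reference value across the parameterizations compatible with the
  other ensemble targets (see the calibration notes above).
* The uniform trait family cannot realize an SD equal to its mean on a
  nonnegative support; the maximal-spread uniform is used instead.
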
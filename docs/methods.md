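# Methods

## Scope and model

`ctqsim` models a single non-preemptive CT scanner serving three
patient classes (GP/UP/EP) over terminating working days. Each day is
one replication: the system opens empty at 8:00 (t = 0 min), arrivals
occur over `open_minutes` (default 780, i.e. until 21:00), and the
scanner works overtime until the line drains, so the daily examination
quantity equals the daily demand and no patient is carried overnight.
There is no balking or reneging, and an exam in progress is never
interrupted — exams are short (≤ 7 min), so preemption would change
little while complicating the state space.

Event handling is deterministic at equal timestamps: a service
completion is processed before a simultaneously occurring arrival, and
the completion's dispatch of the next patient is atomic with it (a
patient arriving at exactly that instant is not yet eligible);
simultaneous arrivals join in draw order. Time is continuous (real
minutes); service durations are integers on the empirical supports.

## Input distributions

* **Examination durations** are empirical discrete distributions on
  whole minutes: GPs on {1..4} with probabilities
  (.111, .579, .249, .061), mean 2.26 min; the emergency stream (EPs
  and UPs alike) on {1..7} with probabilities
  (.024, .341, .320, .155, .075, .061, .024), mean 3.195 min. Sampling
  is inverse-CDF on the cumulative weights.
* **Emergency-stream arrivals** are a homogeneous Poisson process:
  i.i.d. exponential interarrivals with configurable mean
  (`ep_mean_interarrival`, default 7 min). Each arrival is labelled UP
  with probability `urgent_fraction` (default 0.7), independently.
* **GP arrivals** are a nonhomogeneous Poisson process with
  piecewise-constant hourly rates, realized by mapping unit-rate
  exponential gaps through the inverse cumulative intensity
  (equivalently: exponential gaps with boundary carryover), so
  per-interval counts are Poisson and increments independent.

## The synthetic GP profile and its calibration

The real GP arrival-time record is unavailable, so the generator ships
a stand-in: 13 hourly expected counts
(26, 30, 28, 22, 14, 8, 6, 6, 6, 5, 4, 4, 3), totalling 162 GPs/day —
a front-loaded appointment profile whose morning peak exceeds the
scanner's GP-side capacity and builds the multi-hour backlog that the
historical waiting figures imply. A flat profile at the same daily
volume could not produce an hour-long mean GP wait at ρ < 1; the
transient morning overload is the mechanism.

`calibrate()` fits this stand-in to the historical congestion level in
two deterministic steps:

1. The emergency interarrival mean is set so the emergency stream
   supplies its historical share (34.2%) of the target daily total,
   clamped to [7, 9.3] min. The two endpoints reflect an internal
   tension in the source figures: a stated exponential parameter of 7
   implies ≈ 111 emergency-stream patients/day, while a 34.2% share of
   245 implies ≈ 84 (mean ≈ 9.3 min). The daily-total target selects
   9.3; both bounds are configurable.
2. A scalar multiplier on the GP rates is bisected against the mean GP
   wait of `n_pilot` (default 100) base-discipline pilot days run on a
   fixed pilot seed — GP wait is monotone in load, and the fixed seed
   makes the search deterministic and idempotent (recalibrating a
   calibrated profile moves the rates by well under 5%).

Calibration fails explicitly (a `CalibrationError`) when the targets
are infeasible, e.g. a zero wait target at positive load, or a wait
outside ±10% / daily total outside ±5% of target at convergence.
Defaults land at scale ≈ 0.99: achieved GP wait ≈ 66.8 min and
≈ 246 patients/day.

## Disciplines

All three disciplines manipulate an ordered waiting list; the head is
served next except under the aging rule, which rescans at each
dispatch.

* **base** — GPs append; every emergency-class patient (UP counted as
  emergency here) joins immediately behind the last emergency-class
  patient. FIFO within each group.
* **fixed** — EPs join behind the last EP, ahead of every UP and GP
  (absolute precedence). A new UP takes the *marker* — last UP if any,
  else last EP, else the head — counts the GPs behind it, and is
  placed behind exactly `P` of them if more than `P` stand there
  ("more than" strict), otherwise at the end. The patient on the
  scanner never counts. `P` ∈ {0..10}; with P = 0 the GP-side dynamics
  coincide exactly with base (the internal EP/UP order of the
  emergency block may differ, since EPs overtake waiting UPs here).
* **dynamic** — at each dispatch the waiting patient minimizing
  f is served, where f_EP ≡ 1 and f = threshold/wait clamped at 1 for
  UPs (threshold 20) and GPs (threshold 40). A zero wait maps to +∞
  (the limit of threshold/t), so a just-arrived non-emergency patient
  outranks nobody. Because f is a fixed monotone transform of waiting
  time, evaluating it lazily at dispatch instants is equivalent to
  continuous re-ranking.

**Tie-breaking at equal f.** Ties essentially only occur at the
saturated rank f = 1. The default resolves them by urgency class
(EP < UP < GP), then arrival time, then id: emergencies are never
queued behind over-threshold GPs, and an over-threshold UP overtakes
over-threshold GPs. This is the reading consistent with the reference
behaviour of the system (emergency waits stay near 1.5 min and urgent
waits near their 20-min threshold under the aging rule). The
alternative — global FIFO among tied patients — is available as
`PolicyConfig(tie_break="arrival")`; under midday backlog it makes
over-threshold GPs block later emergencies, inflating EP waits by an
order of magnitude.

## Output analysis

Per day: per-class and overall mean waits (the overall mean satisfies
the count-weighted identity exactly), satisfaction rates — fraction of
a class whose wait is *within* (≤, inclusive boundary) its threshold;
EPs have no finite threshold and are excluded — daily quantity, and
the fraction of UPs pushed past their threshold. Across replications:
mean, standard deviation, and Student-t 95% confidence intervals
(n − 1 df). Indicators undefined on a day (no patient of a class) are
excluded from that indicator's average.

Policy comparisons use common random numbers: the arrival and duration
streams of a replication are drawn once — from substreams keyed by
`(master_seed, replication, stream_name)`, never by policy — and
replayed under every discipline, so column differences are paired.

## Problem sizes and determinism

The shipped experiments use 100 replications per discipline (and 100
pilot days per calibration step), ≈ 245 patients/day; a full
13-discipline sweep takes a few seconds on one core. Every run is
bit-reproducible from `(master_seed, n_reps)` plus the package
version; the CLI writes a manifest capturing both.

## What the synthetic stand-in does and does not show

Passing results demonstrate the comparative behaviour of the
disciplines *under the calibrated synthetic conditions*: a morning-peak
nonhomogeneous Poisson GP stream, a stationary Poisson emergency
stream, day-independent replications, and exact threshold values.
Real arrival records have features the stand-in lacks — day-of-week
and seasonal structure, correlated batch arrivals, duration/class
dependence, schedule-driven (non-Poisson) appointment clumping — so
absolute magnitudes transfer only approximately; the direction and
ordering of policy effects are the robust conclusions.

One reference figure is structurally out of reach and is reported
red rather than tuned toward: the claimed ~13-minute cut in mean GP
wait under the aging rule alongside urgent waits held under 20 min.
The scanner is work-conserving, so reordering can reduce *total*
waiting only through the shortest-processing-time effect (GP exams
average 2.26 min vs 3.195 for the emergency stream — worth roughly
1 min/patient here); beyond that, every GP-minute saved must be paid
by UPs or EPs. With ≈ 59 UPs each deferrable by at most ~18 min
against ≈ 161 GPs, the GP-side gain is bounded near 7–8 min even if
every UP were held at its full threshold all day; the measured value
on the calibrated profile is ≈ 5 min (with mean UP wait ≈ 12 min).
The corresponding satisfaction gain is likewise moderate (GP
satisfaction rises by ~4 percentage points, not tens).

## Known limitations

Single scanner only (no multi-machine synergy); no within-day
nonstationarity in the emergency stream; durations independent of
class load and time of day; thresholds are sharp constants; no
patient abandonment. The calibration searches a single scalar on the
GP profile — it matches the target mean wait and volume, not the full
waiting-time distribution.
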
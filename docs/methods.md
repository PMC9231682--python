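# Methods

## The measurement model

A pendant accelerometer hung between a spring-loaded feed-bunk door and
the bunk divider records static acceleration on three axes at a fixed
epoch (default 30 s). For the gravity-referenced axis, tilt is
`180° − arccos(a)` with `a` in units of g, so `a = −1` (hanging straight
down) is 0°, `a = 0` is 90° and `a = +1` is 180°. Sensor noise can push
|a| marginally past 1, where arccos is undefined; values within a 0.05 g
tolerance are clipped to ±1 (and counted), anything beyond that is
treated as a unit error (e.g. m/s² instead of g) and rejected.

The door reads ~0° closed and well above 60° open. The open threshold of
30° splits those modes with margin for *sag*: the mount slowly loses
tension, lifting the closed-door baseline by a few degrees until it is
re-tightened. The boundary is inclusive on the open side (tilt ≥ 30° ⇒
open). Sag QC counts samples strictly between 0° and the threshold.

Records are segmented into experimental days at a local clock boundary
(05:00 default — cows are locked out of the bunks then, so the boundary
falls in forced-closed time). Timestamps are naive local time: loggers in
one deployment are launched from one computer, and DST arithmetic would
add complexity with no benefit at 7-day missions. Data gaps longer than
two epochs are flagged and break runs; states are never interpolated
across a gap, and closed time touching a gap (or a day edge) is censored
rather than counted as an interval, because its true extent is unknown.

## Intervals and the meal criterion

Closed bouts flanked by feeding bouts are between-feeding intervals.
Intervals shorter than 2 min are excluded before model fitting: at a 30-s
epoch that regime is undersampled (many true pauses are shorter than one
epoch) and would distort the left tail. The survivors are modelled on the
natural-log-seconds scale as a K-component Gaussian mixture; K = 2 and 3
are compared. Interpretation of the components, left to right: within-meal
pauses surviving the cutoff, drink/idle pauses, and true between-meal
gaps.

The EM fitter is univariate: quantile-based initial means at the
(i + ½)/K quantiles, pooled SD, uniform weights; 10 restarts with
mean jitter of half the pooled SD; convergence at a log-likelihood change
below 1e−8 or 500 iterations, with a hard assertion that the likelihood
never decreases (slack 1e−7 for float noise). A component whose SD or
weight collapses aborts that run; if every restart collapses the fit
fails. This matters in practice: durations are multiples of the epoch, so
the filtered data contain an atom at exactly ln(120 s) and, on small
datasets, the likelihood is unbounded along a component shrinking onto
it. The pipeline therefore skips candidates whose restarts all degenerate
(recording the failure in the run report) instead of aborting, and
selects among the models that did fit.

Model choice uses AICc (= −2LL + 2k + 2k(k+1)/(n−k−1)) and BIC
(= −2LL + k ln n) with k = 3K − 1 free parameters (K means, K SDs, K−1
weights) and n the post-filter interval count; this parameter-counting
convention is the one under which the published model comparison for this
system is internally consistent. The default selection rule is BIC; ties
go to the earlier candidate.

The minimum intermeal interval is the crossing C of the *unit-mass*
densities of the two rightmost components: equating log-densities gives
a quadratic with exactly one root in (μ₁, μ₂) for well-separated
components; when |σ₁ − σ₂| < 1e−9 the quadratic degenerates and the limit
(μ₁ + μ₂)/2 is used. The component weights are deliberately not part of
the criterion — the convention in this literature uses only μ and σ — but
a weighted-density variant (solved by bisection, since the weighted
equation has no closed form that is simpler than the root-find) is
available behind a flag for sensitivity analysis. The returned root is
asserted to equalize the two densities to 1e−8.

## Meals

Feeding bouts separated by closed gaps shorter than the MII merge; a gap
≥ MII splits (the strict/inclusive choice is immaterial at 30-s
resolution except on a measure-zero boundary). Meal *length* is the
wall-clock span from the start of the first merged bout to the end of the
last — within-meal gaps count toward length, which is the reading
consistent with mean meal lengths far exceeding plausible continuous
door-open time — and the summed open time is carried alongside for users
who prefer the other reading. Meals spanning the day boundary belong to
the day containing their start. Meals of ≤ 30 s (one epoch) are removed:
a single-sample presence cannot be confirmed as feeding throughout.
Increasing the MII provably never increases the meal count, and the total
open time is invariant to the MII; both are enforced as tests.

## Observer agreement

Each observer record is paired with the sensor sample nearest in absolute
time (ties to the earlier sample) and that sample's value is replaced by
the mode of the window from 5 samples before to 5 after — an 11-sample
centered window; the odd width precludes interior ties, and truncated edge
windows break ties toward the raw value. The windowed mode exists to
absorb the disturbance the observer's own presence causes; it is applied
in the validation alignment only, not in the main pipeline (a config flag
can enable global smoothing). Note a structural consequence: the mode
erases genuine bouts shorter than half the window, so perfect agreement
is only expected when all runs are long relative to 11 samples — the
noise-free validation scenario in the tests uses meal-scale bouts for
exactly this reason.

Kappa, its asymptotic variance and the 95% CI come from statsmodels'
two-rater implementation; PPV = n11/(n11+n10) and NPV = n00/(n00+n01)
are computed directly, with a zero denominator yielding NaN (flagged, not
fatal). The three observers of a live validation are treated as one
reference stream per door; multi-rater agreement is out of scope.

## Logger planning

Fill time = (memory − header) / (samples_per_s × axes). Capacity is
interpreted in *sample slots* (≈65,000, with a ≈500-slot output header),
the only reading under which the vendor-quoted figures reproduce the
~7.5-day mission that a 30-s, 3-axis deployment actually achieves; the
report carries this interpretation note.

## The simulator and what it does (not) show

`simulate` draws, per cow-day, an alternating renewal process inside the
feeding window (feed delivered 3 h after the 05:00 lockout, i.e. a 21-h
window): log-normal feeding bouts (median 300 s, σ_log 0.5) alternating
with closed gaps from a three-component log-normal mixture, all durations
rounded to the epoch grid. Gap components sit at μ = (4.0, 6.34, 8.77),
σ = (0.6, 0.61, 0.63) log-seconds — the rightmost two equal the published
fit for this system, the leftmost (exp(4.0) ≈ 55 s) populates the
sub-2-min regime the filter must absorb. The weights (0.69, 0.19, 0.12)
were derived analytically, not tuned: requiring (i) mixture mass below
120 s of ≈0.63 and (ii) an expected meal frequency of ≈7.3 meals/d at a
31.3-min criterion (≈6.3 between-meal gaps per 21-h window given the
cycle-length algebra) pins them to within rounding. Tilt is rendered as
closed baseline + linear sag (8°/day, reset twice daily, capped at 10°,
i.e. always below the 30° threshold) or the 70° open angle, plus 1°
Gaussian noise; the observer samples the true state every 170 s with
±20 s jitter and an optional label-flip rate. Every draw descends from
the single config seed via per-cow substreams.

What the simulator does *not* emulate: social displacement at the bunk,
door bounce/partial openings, battery failures and detachment (gaps can
be injected but are not part of the default process), observer fatigue,
and any link between presence and actual intake. Passing end-to-end tests
therefore show the *algorithms* recover planted structure under realistic
noise — not that a particular herd's criterion is 31.3 min.

## Problem sizes in the test suite

Replicate counts and herd sizes in the tests are the package's own
choices to keep the suite quick while leaving the checks sharp: EM
parameter recovery uses 20 replicates at n = 6,494 (the published fitted
count); model-count recovery uses 20 replicates at n = 3,000; end-to-end
criterion recovery uses a 16-cow × 7-day deployment (≈6,000 raw gaps,
≈2,400 fitted); the herd-scale meal-frequency check uses the full
48 × 7 visit process. The closed-form intersection is cross-checked
against a bisection oracle on 200 random parameter sets with means at
least 1 log-unit apart and SDs in [0.2, 0.9] — the separation regime in
which exactly one crossing lies between the means (outside it, a crossing
between the means need not exist, and the code raises instead).

## Known limitations

* The criterion presumes the two rightmost components are separated and
  log-normal-ish; herds or systems whose drink pauses merge into meals
  will need K = 2 or a different decomposition.
* Discretized durations make small-sample K = 3 fits fragile (the
  ln(120 s) atom); with a few hundred intervals, expect the pipeline to
  fall back to K = 2.
* κ's asymptotic CI is anti-conservative for very small tables.
* The system observes presence at the gate, not ingestion; "meal" here
  means a bout of presence.
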
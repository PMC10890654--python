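# Methods

## Course and data model

A race is an ordered sequence of lap split times on a loop course. The
course is modelled as `n_laps` *equal* laps of `total_distance / n_laps`
metres (default 33 × 1278.64 m = 42,195 m). The real loop is only nominally
~1279 m (33 × 1279 = 42,207 ≠ 42,195); because every pacing variable is a
ratio of speeds, it is invariant to the assumed lap length, and the equal-lap
model removes the 12 m inconsistency without affecting any percentage
variable. Within a lap, speed is taken as constant (linear interpolation of
time in distance) — no finer-grained data exist. `time_at_distance` and
`segment_mean_speed` build on this to evaluate the mid-race and last-10-km
boundaries, which generally fall inside a lap.

Race mean speed is total distance over finish time (the time-weighted mean of
lap speeds), never the arithmetic mean of lap speeds; the arithmetic mean is
always ≥ the time-weighted mean, which is why the signed CS variable is
non-negative by construction.

## Pacing variables: conventions

* **sd denominator.** CV uses the sample sd (n−1), matching the defaults of
  the statistics packages practitioners use. With 33 laps the difference
  from the population sd is ~1.5% of the value.
* **Sign convention.** CSF, MRS and 32-10 compare an earlier against a later
  segment. The default is slowdown-positive — (earlier speed − later speed)
  / earlier speed — so the common positive-pacing (fading) profile produces
  positive values, consistent with how these variables are tabulated in the
  field. The literal later-minus-earlier reading is available via
  `sign="literal"` and simply negates the three variables.
* **CSF** averages over all laps including lap 1, which contributes zero.
* **MRS halves** are defined by distance (D/2), not lap count (33 is odd).
* **32-10 boundary** is exactly D − 10,000 m (32,195 m on a marathon),
  interpolated within the containing lap. On courses ≤ 10 km the variable is
  undefined; the strict function raises and the batch path records NaN.

## Profile classification

Ordinary least squares of lap speed on lap index 1..n. Under equal laps the
index is affine in cumulative distance, so the correlation r is identical
either way. Labels: r < −0.1 positive, r > 0.1 negative, otherwise even —
the boundary values ±0.1 classify as even (the inclusive reading avoids an
undefined gap). A zero-variance record has no defined r; it is reported as
r = 0, even, with a `degenerate` flag. Fisher's Z = atanh(r) feeds the
across-day repeated-measures ANOVA; |r| ≥ 1 (a perfectly linear race) is
clamped to 0.999999 with a warning rather than propagating ±∞.

## Reliability battery

For each variable the complete runners × days matrix is decomposed as
SST = SSR (subjects) + SSC (days) + SSE, with the day effect tested by
F = MSC/MSE on df (k−1, (n−1)(k−1)). No sphericity correction is applied by
default (a plain F is the field's convention for these panels); components
smaller than 1e−12 of SST are treated as exactly zero so that degenerate
matrices (identical columns, pure row+column structure) produce exact
F = 0/p = 1 or a flagged infinite F rather than floating-point residue.

* **ICC.** Default ICC(3,1), two-way mixed, single measures, consistency:
  (MSR − MSE)/(MSR + (k−1)MSE), with the 95% CI from the standard F-based
  closed form. This is the conventional model for repeated performances by
  the same athletes, where a uniform day shift should not count against
  reliability. ICC(2,1) (absolute agreement, McGraw–Wong CI) is available by
  option. Both are cross-checked against pingouin in the test suite.
  Interpretation bands: poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤
  excellent.
* **SEM** = pooled sd × √(1 − ICC), with the pooled sd computed over all
  cells after removing day means — consistent with the consistency ICC.
* **Typical-error CV%.** RM-ANOVA on 100·ln(x); typical error s = √MSE;
  CV% = 100·(exp(s/100) − 1). Signed variables (CS, MRS, 32-10) can be
  negative, making the log transform impossible in general; such matrices
  automatically fall back to the raw-scale typical error divided by the
  grand mean, flagged `transform_used = "raw"` in the report.

## Validity, sensitivity, groups

Pearson r (two-sided t-based p) of each variable against CV per day
(validity) and of CV/ACS/PR against mean speed per day (sensitivity).
CS, CSF, MRS and 32-10 are excluded from the sensitivity battery by default
because of their poor reliability; the selection is overridable. Correlation
magnitude bands: small 0.10, moderate 0.30, large 0.50.

Performance groups are Fast/Medium/Slow on the mean marathon time across
days. The default binning uses explicit time boundaries (4:01:17 and
4:37:08); rank-tertiles (earlier groups take the extra runner, ties broken
by runner id) are the general-purpose alternative, and the pipeline falls
back to tertiles with a logged notice when a boundary group has fewer than
two members. The group comparison is a one-way between-groups ANOVA with
η² = SS_between/SS_total and LSD post-hoc pairwise t-tests on the pooled
within-group mean square — deliberately unadjusted, which is what the LSD
procedure means. No multiple-testing correction is applied across variables
or days.

## Synthetic cohort generator

Lap speed for runner r, day d, lap k of L:

    v = B_r · (1 + δ_{r,d}) · (1 + s_r·(k − (L+1)/2)/L) · (1 + ε_{r,d,k}) · spurt_k

with per-runner base speed `B_r ~ N(2.72, 0.32²)` m/s truncated above 1 m/s,
day effect `δ ~ N(0, 0.01²)`, linear drift `s_r ~ N(−0.10, 0.04²)` held
constant across days, lap noise `ε ~ N(0, σ_r²)` with
`σ_r = 0.055 · (2.72/B_r)^1.5`, and an end-spurt multiplier 1.03 on the last
2 laps. Defaults encode the emulated field: 20 finishers over 4 days at a
cohort mean speed of ≈ 2.72 ± 0.32 m/s, within-race lap CV in the 6–7% band,
predominantly positive profiles that are stable within a runner
(drift constant across days), small day effects, an end spurt, and more
lap-to-lap noise in slower runners (the coupling exponent 1.5 produces
CV-vs-MS correlations in the −0.3 to −0.7 range typical of recreational
fields). Negative sampled speeds are redrawn (bounded retries); identical
(config, seed) reproduce the cohort byte-for-byte.

The generator is deliberately simple: drift is linear (matching the linear
profile classifier), there is no cumulative multi-day fatigue, no weather,
no mid-race surges, and lap noise is Gaussian and independent across laps.
Passing tests therefore demonstrate that the statistical machinery recovers
a known generative structure — not that real races obey that structure.

`expected_within_race_cv` is the first-order prediction
`100·√(lap_noise_cv² + (drift_mean² + drift_sd²)·Var((k−(L+1)/2)/L))`,
ignoring the end spurt and the noise-speed coupling; tests hold it to within
one CV point of the simulated cohort mean.

## Problem sizes and numerical choices

The test suite and the acceptance script use the default cohort size
(20 × 4 × 33), a 200-runner cohort for ICC parameter recovery, and 50 seeds
for the coupling sign test — sizes at which the Monte-Carlo error of each
checked quantity is well inside its asserted tolerance, while the whole
suite runs in seconds. ICC recovery is asserted to within 0.02 of the
variance-component prediction (the prediction itself carries a small bias
because it evaluates the noise coupling at the mean base speed). Degenerate
inputs (zero-variance variables, identical columns, single-day cohorts) are
flagged or skipped with explicit notices rather than producing NaNs.

## Known limitations

* The equal-lap assumption cannot be checked against the real course; if the
  final lap were physically shorter, absolute speeds (not the percentage
  variables) would shift slightly.
* The typical-error CV% of percentage-valued variables depends on the exact
  back-transform pipeline; conventions differ between published panels, and
  this module documents its own (Hopkins-style 100·ln) rather than claiming
  to reproduce any specific published cell.
* LSD post-hoc tests and the per-day correlation batteries are intentionally
  uncorrected for multiplicity; with 6 variables × 4 days, some nominally
  significant correlations are expected by chance.
* Group binning by explicit boundaries presumes the cohort spans those
  boundaries; skewed synthetic cohorts trigger the tertile fallback.
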
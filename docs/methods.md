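# Methods

## Scope and model

`stepagree` quantifies the agreement between consumer step-count devices and
a research reference accelerometer over a multi-day free-living window. The
unit of analysis is the per-participant step total over the analysis window
(default 72 h), not per-day counts: free-living step data are highly skewed
across participants, and the window total is what the limits of agreement
and the MAD statistic are defined on.

The sign convention is fixed throughout: differences are
`reference − tracker`, so a positive bias means the tracker undercounts.

### Bland–Altman

Bias is the mean difference, spread is the sample SD of the differences
(n−1 denominator), and the 95% limits of agreement are `bias ± 1.96 × SD`.
The multiplier is exactly 1.96 rather than a t-quantile; with n ≈ 30 the
difference is immaterial and published tables of this design reproduce to
the step with 1.96. The multiplier is exposed as a parameter. Reported
tables round steps to integers and MAD to one decimal percent; full
precision is retained internally and in the JSON output.

### MAD%

`median(|tracker − reference| / reference) × 100`. The reference total must
be positive for every retained pair (enforced at aggregation; a participant
whose cleaned reference total is zero is excluded with a reason, not
zero-filled). Even n uses the mean of the two central order statistics — no
special tie handling.

### LOOCV bias correction

With one participant per fold (k = n), each fold estimates the bias on the
other n−1 pairs and applies it to the held-out tracker total. The default
correction is additive (tracker + training bias), matching the Bland–Altman
bias definition; a proportional variant (tracker × training mean-ratio) is
available behind the `--correction` flag. The corrected MAD is the MAD of
the held-out corrected pairs; per-fold biases are retained for audit.
Behaviourally: when a device's error is dominated by a constant offset the
corrected MAD collapses toward the noise floor; when between-participant
variance dominates, correction yields no material improvement — both regimes
are pinned by tests.

## Cleaning

Wear status is decided on the reference only: maximal runs of consecutive
zero-step minutes of length ≥ `--nonwear-min-run` (default 60, strict — no
interruption tolerance) are nonwear. Sixty minutes of literal zeros is the
simplest defensible convention; proprietary actigraphy software may tolerate
brief interruptions, so the threshold is a surfaced parameter rather than a
constant. The mask is applied to all devices of that participant by
wall-clock interval (tracker epochs are irregular, so epoch indices are
meaningless across devices). Epochs partially overlapping nonwear keep
`round(steps × worn_fraction)` — the within-epoch placement of steps is
unknown, so proportional allocation is the neutral choice. One consequence,
deliberate and documented: devices with very coarse epochs (multi-hour sync
intervals) lose a proportional share of steps at mask boundaries even when
the steps actually fell in worn time. Day-length diary epochs (≥ 720 min)
are the exception — a once-per-day display reading cannot be sub-day masked
and already reflects only worn time, so they are kept whole (or dropped
wholesale when a whole day is nonworn).

The analysis window is each participant's reference coverage (pre-masking)
truncated to `--window-hours`; a reference stream with missing trailing
hours shortens that participant's window rather than being imputed. Epoch
membership in the window is by epoch start, half-open `[start, end)`;
timestamps are timezone-naive local time with day boundaries at midnight.
Pairs are dropped, with a reason written to `exclusions.csv`, when a device
stream is absent, empty within the window, or the reference total is zero;
a tracker that lost one day still contributes a pair over its remaining
data (the reference-defined worn set is the shared wall-clock frame; missing
tracker epochs inside it are absent data, not nonwear).

## Synthetic data

The generator's defaults describe a realistic 30-participant × 72-hour
free-living study and are not tuned per run.

**Ground truth** is minute-resolution. Walking bouts start as a Poisson
process within the waking window (default 08:00–22:00); each bout lasts a
fixed `bout_duration` (default 6 min); per-minute cadence is Normal
(default 90 ± 12 steps/min, truncated at 0, rounded); minutes outside bouts
carry Poisson incidental steps (default 2/min); sleep is in-window zero-step
time. When `daily_total_target` is set, the bout rate is solved from the
coverage relation `covered = W(1 − exp(−λd/W))` so that
`background·(W − covered) + covered·cadence` equals the target — the
expected total is therefore available in closed form and the Monte-Carlo
mean matches it (tested). Per-participant targets are log-normal with
median 21,527/3 steps/day and log-SD 0.20, placing the simulated cohort's
72-h totals at median ≈ 21.5k with ≥ 95% inside 10,757–35,818 — the range
reported for healthy adults in comparable validation work.

**Observation** re-bins the truth to the device's update interval: fixed
k-minute bins; "variable" bins from exponential gaps (quantized to whole
minutes, mean set from observed data-point counts, e.g. ≈ 9.25 min for a
smartwatch delivering ~467 points per 72 h); or "daily" diary bins. Scaling
by `1 − undercount_fraction` uses cumulative-sum rounding so the re-binned
total equals `round((1−u) × true total)` exactly — expectations in tests are
exact when noise is off. Per-epoch Gaussian noise applies only to epochs
with nonzero binned steps (devices report nothing while idle), with
defaults small relative to typical epoch counts so zero-clipping does not
inflate totals. Cadence-dependent misses drop sub-threshold minutes with a
configurable probability; no published per-device miss rates exist, so the
defaults leave this off. Whole calendar days are lost with
`malfunction_day_prob`; `battery_death_prob` truncates the stream at a
uniform point. The carryover artifact adds a uniform integer from
`carryover_steps_range` to the first surviving epoch of each calendar day,
mimicking trackers that fail to reset to zero overnight.

**What the simulator does not emulate:** wear-site (wrist vs hip)
differences, intensity-dependent accuracy beyond the threshold miss model,
vendor export formats, and — by default — the large *between-participant*
spread of device error seen in real studies (per-epoch noise is kept
unbiased and modest, so simulated difference SDs are smaller than published
ones). Passing tests therefore demonstrate the correctness of the cleaning
and statistics machinery under the stated error models, not that any real
device meets a given MAD.

## Determinism and numerics

Every stochastic component takes a seed; studies derive per-(participant,
device) seeds from the config seed via `numpy.random.SeedSequence.spawn`,
so identical configs give byte-identical output files. Validation reports
are byte-stable across runs (sorted JSON keys, fixed timestamp format) and
carry a SHA-256 hash over the manifest, stream files and options.
Degenerate inputs fail loudly: fewer than 2 pairs for Bland–Altman, fewer
than 3 for LOOCV, nonpositive reference totals for MAD, coarse epochs where
minute resolution is required.

## Problem sizes

The test suite simulates cohorts at the study's native scale (30
participants, 72 h, minute resolution) where a claim depends on it — cohort
calibration uses 100 seeds × 30 participants; bias recovery uses 500
replicate studies of 30 paired totals drawn directly at the totals level,
where the epoch machinery adds nothing to the estimand.
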
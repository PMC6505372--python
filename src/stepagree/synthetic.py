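"""Synthetic free-living activity and device-observation simulator.

The study design this package targets — several consumer trackers worn
simultaneously with a research accelerometer for 72 hours of unscripted daily
life — rarely comes with released raw data.  This module generates data with
the same statistical structure so that every stage of the pipeline can be
exercised end to end.

Ground truth is a minute-resolution bout process: walking bouts start as a
Poisson process within each day's waking window, each bout lasts a fixed
number of minutes, and per-minute cadence is Normal (truncated at zero).
Minutes outside bouts but inside the waking window carry Poisson "incidental"
steps; sleep is in-window zero-step time.  A :class:`DeviceErrorModel` then
maps the truth to what a device reports: re-binning to the device's update
interval (fixed, exponential-gap "variable", or once-per-day diary style),
systematic under/over-count, per-epoch noise, cadence-dependent missed steps,
whole lost days, battery death, and an overnight step-carryover artifact
(phantom steps appearing in the first epoch of a day).
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .models import ResolutionError, StepStream

DEFAULT_START = pd.Timestamp("2016-06-06 00:00:00")

#: Median and log-scale spread of the per-participant daily step target used
#: when a study config does not pin profiles explicitly.  The median matches a
#: typical healthy-adult 72-hour reference total of ~21,500 steps.
DEFAULT_DAILY_TARGET_MEDIAN = 21_527 / 3
DEFAULT_DAILY_TARGET_SIGMA = 0.20


class ActivityProfile(BaseModel):
    """Parameters of one participant's free-living activity process.

    ``daily_total_target``, when set, rescales the bout rate so that the
    expected steps per day equals the target (accounting for bout overlap);
    ``bout_rate`` is then ignored.
    """

    n_days: int = Field(default=3, ge=1)
    waking_start: float = Field(default=8.0, ge=0.0, lt=24.0)
    waking_end: float = Field(default=22.0, gt=0.0, le=24.0)
    bout_rate: float = Field(default=0.5, ge=0.0)  # bouts per waking hour
    bout_duration: float = Field(default=6.0, gt=0.0)  # minutes per bout
    cadence_mean: float = Field(default=90.0, ge=0.0)  # steps/min in bouts
    cadence_sd: float = Field(default=12.0, ge=0.0)
    background_rate: float = Field(default=2.0, ge=0.0)  # steps/min off-bout
    daily_total_target: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _check_window(self) -> "ActivityProfile":
        if self.waking_start >= self.waking_end:
            raise ValueError("waking_start must be earlier than waking_end")
        return self

    @property
    def waking_minutes_per_day(self) -> int:
        return int(round((self.waking_end - self.waking_start) * 60))

    def expected_bouts_per_day(self) -> float:
        """Poisson mean of bout starts per full day.

        When a daily target is set, invert the coverage relation
        ``covered = W * (1 - exp(-lam * d / W))`` (W waking minutes, d bout
        length, lam expected bouts) so that the expected daily total —
        background plus covered-minute cadence — equals the target exactly.
        """
        W = self.waking_minutes_per_day
        d = max(1, int(round(self.bout_duration)))
        if self.daily_total_target is None:
            return self.bout_rate * (self.waking_end - self.waking_start)
        background = self.background_rate * W
        # covered minutes step at cadence_mean instead of background_rate
        net_cadence = self.cadence_mean - self.background_rate
        if net_cadence <= 0:
            if self.daily_total_target > background:
                raise ValueError(
                    "daily_total_target unreachable: cadence_mean must exceed "
                    "background_rate"
                )
            return 0.0
        covered = (self.daily_total_target - background) / net_cadence
        if covered <= 0:
            return 0.0
        if covered >= W:
            raise ValueError(
                "daily_total_target exceeds what the waking window can hold"
            )
        return -(W / d) * math.log1p(-covered / W)

    def expected_total(self, window_hours: float | None = None) -> float:
        """Closed-form expected steps over the window (default: ``n_days``)."""
        if window_hours is None:
            window_hours = self.n_days * 24
        W = self.waking_minutes_per_day
        d = max(1, int(round(self.bout_duration)))
        lam = self.expected_bouts_per_day()
        covered = W * -math.expm1(-lam * d / W)
        per_day = (
            self.background_rate * (W - covered) + covered * self.cadence_mean
        )
        return per_day * window_hours / 24.0


class DeviceErrorModel(BaseModel):
    """Observation process mapping true minute steps to a device's report.

    ``update_interval`` is a fixed number of minutes, ``"variable"``
    (exponential gaps with mean ``variable_mean_minutes``, quantized to whole
    minutes), or ``"daily"`` (one epoch per calendar day, diary style).
    ``undercount_fraction`` is the expected proportion of true steps the
    device misses; negative values model systematic over-count.
    """

    update_interval: int | Literal["variable", "daily"] = 1
    variable_mean_minutes: Optional[float] = Field(default=None, gt=1.0)
    undercount_fraction: float = Field(default=0.0, gt=-1.0, lt=1.0)
    epoch_noise_sd: float = Field(default=0.0, ge=0.0)
    low_cadence_miss_threshold: float = Field(default=0.0, ge=0.0)
    low_cadence_miss_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    carryover_enabled: bool = False
    carryover_steps_range: tuple[int, int] = (0, 0)
    malfunction_day_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    battery_death_prob: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("update_interval")
    @classmethod
    def _check_interval(cls, v):
        if isinstance(v, int) and v < 1:
            raise ValueError("fixed update_interval must be >= 1 minute")
        return v

    @model_validator(mode="after")
    def _check_model(self) -> "DeviceErrorModel":
        if self.update_interval == "variable" and self.variable_mean_minutes is None:
            raise ValueError("variable update_interval requires variable_mean_minutes")
        lo, hi = self.carryover_steps_range
        if lo < 0 or hi < lo:
            raise ValueError("carryover_steps_range must satisfy 0 <= min <= max")
        return self

    @property
    def is_identity(self) -> bool:
        return (
            self.update_interval == 1
            and self.undercount_fraction == 0.0
            and self.epoch_noise_sd == 0.0
            and self.low_cadence_miss_prob == 0.0
            and not self.carryover_enabled
            and self.malfunction_day_prob == 0.0
            and self.battery_death_prob == 0.0
        )


class StudyConfig(BaseModel):
    """Full multi-device study: participants, profiles, devices, seed."""

    n_participants: int = Field(default=30, ge=2)
    window_hours: int = Field(default=72, ge=1)
    seed: int = 0
    reference_device: str = "actigraph"
    device_models: dict[str, DeviceErrorModel]
    profiles: Optional[list[ActivityProfile]] = None
    #: explicit device-off intervals per participant id, as ISO timestamp pairs
    nonwear: dict[str, list[tuple[str, str]]] = Field(default_factory=dict)
    start: str = str(DEFAULT_START)

    @model_validator(mode="after")
    def _check_config(self) -> "StudyConfig":
        if self.reference_device not in self.device_models:
            raise ValueError(
                f"reference_device {self.reference_device!r} not in device_models"
            )
        if self.profiles is not None and len(self.profiles) != self.n_participants:
            raise ValueError("profiles must have one entry per participant")
        return self


def participant_label(i: int) -> str:
    return f"p{i + 1:02d}"


def generate_ground_truth(
    profile: ActivityProfile,
    window_hours: float | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    participant_id: str = "truth",
    device_id: str = "truth",
    start: pd.Timestamp | str = DEFAULT_START,
) -> StepStream:
    """Simulate one participant's true minute-resolution step stream.

    The stream covers ``window_hours`` from ``start`` at 1-minute epochs; all
    minutes outside the profile's waking window are zero (sleep).
    """
    if window_hours is None:
        window_hours = profile.n_days * 24
    if window_hours < 1:
        raise ValueError("window_hours must be >= 1")
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start)
    n_min = int(round(window_hours * 60))
    minutes = t0 + pd.to_timedelta(np.arange(n_min), unit="m")
    hour_of_day = minutes.hour + minutes.minute / 60.0
    waking = (hour_of_day >= profile.waking_start) & (hour_of_day < profile.waking_end)
    day_index = ((minutes - t0.normalize()) // pd.Timedelta(days=1)).astype(int)

    steps = np.zeros(n_min, dtype=np.int64)
    in_bout = np.zeros(n_min, dtype=bool)
    lam_full_day = profile.expected_bouts_per_day()
    d = max(1, int(round(profile.bout_duration)))
    W = max(1, profile.waking_minutes_per_day)

    for day in np.unique(day_index):
        idx = np.flatnonzero(waking & (day_index == day))
        if idx.size == 0 or lam_full_day == 0.0:
            continue
        lam = lam_full_day * idx.size / W  # scale for partial days
        n_bouts = rng.poisson(lam)
        if n_bouts == 0:
            continue
        starts = rng.integers(0, idx.size, size=n_bouts)
        for s in np.sort(starts):
            stop = min(s + d, idx.size)  # bouts truncate at the waking end
            in_bout[idx[s:stop]] = True

    n_bout_min = int(in_bout.sum())
    if n_bout_min:
        if profile.cadence_sd > 0:
            cad = rng.normal(profile.cadence_mean, profile.cadence_sd, n_bout_min)
        else:
            cad = np.full(n_bout_min, profile.cadence_mean)
        steps[in_bout] = np.maximum(np.rint(cad), 0).astype(np.int64)
    off_bout = waking & ~in_bout
    if profile.background_rate > 0 and off_bout.any():
        steps[off_bout] = rng.poisson(profile.background_rate, int(off_bout.sum()))

    epochs = pd.DataFrame(
        {"epoch_start": minutes, "epoch_minutes": 1, "steps": steps}
    )
    return StepStream(participant_id, device_id, epochs)


def _round_preserving_total(x: np.ndarray) -> np.ndarray:
    """Round nonnegative floats to ints so the total equals round(sum)."""
    cum = np.round(np.cumsum(x))
    return np.diff(cum, prepend=0.0).astype(np.int64)


def observe(
    truth: StepStream,
    model: DeviceErrorModel,
    seed: int | np.random.SeedSequence = 0,
    *,
    device_id: str | None = None,
) -> StepStream:
    """Apply a device's observation process to a minute-resolution truth stream."""
    if not truth.is_minute_resolution:
        raise ResolutionError(
            f"stream {truth.participant_id}/{truth.device_id}: observation "
            "requires 1-minute epochs"
        )
    rng = np.random.default_rng(seed)
    n = len(truth)
    starts = truth.epochs["epoch_start"]
    steps_true = truth.epochs["steps"].to_numpy(dtype=float)
    s = steps_true.copy()

    # cadence-dependent missed minutes, then systematic under/over-count
    if model.low_cadence_miss_prob > 0 and model.low_cadence_miss_threshold > 0:
        cand = (s > 0) & (s < model.low_cadence_miss_threshold)
        drop = cand & (rng.random(n) < model.low_cadence_miss_prob)
        s[drop] = 0.0
    s *= 1.0 - model.undercount_fraction

    # re-bin to the device's reporting epochs
    minute_idx = np.arange(n)
    t0 = starts.iloc[0]
    day_index = ((starts - t0.normalize()) // pd.Timedelta(days=1)).astype(int).to_numpy()
    if model.update_interval == "daily":
        _, bin_id = np.unique(day_index, return_inverse=True)
    elif model.update_interval == "variable":
        gaps: list[int] = []
        total = 0
        while total < n:
            g = max(1, int(round(rng.exponential(model.variable_mean_minutes))))
            gaps.append(g)
            total += g
        boundaries = np.cumsum(gaps)
        bin_id = np.searchsorted(boundaries, minute_idx, side="right")
    else:
        bin_id = minute_idx // int(model.update_interval)

    n_bins = int(bin_id.max()) + 1 if n else 0
    binned = np.bincount(bin_id, weights=s, minlength=n_bins)
    bin_first = np.full(n_bins, n, dtype=np.int64)
    np.minimum.at(bin_first, bin_id, minute_idx)
    bin_minutes = np.bincount(bin_id, minlength=n_bins)
    epoch_steps = _round_preserving_total(binned)
    epoch_start = starts.to_numpy()[bin_first]
    epoch_day = day_index[bin_first]

    if model.epoch_noise_sd > 0:
        nz = epoch_steps > 0  # devices report nothing while idle; leave zeros alone
        noise = rng.normal(0.0, model.epoch_noise_sd, int(nz.sum()))
        epoch_steps = epoch_steps.astype(np.int64)
        epoch_steps[nz] = np.maximum(
            np.rint(epoch_steps[nz] + noise), 0
        ).astype(np.int64)

    keep = np.ones(n_bins, dtype=bool)
    if model.malfunction_day_prob > 0:
        for day in np.unique(epoch_day):
            if rng.random() < model.malfunction_day_prob:
                keep &= epoch_day != day
    if model.battery_death_prob > 0 and rng.random() < model.battery_death_prob:
        cutoff = rng.integers(0, n)
        keep &= bin_first < cutoff
    if model.carryover_enabled:
        lo, hi = model.carryover_steps_range
        for day in np.unique(epoch_day[keep]):
            first = np.flatnonzero(keep & (epoch_day == day))[0]
            epoch_steps[first] += int(rng.integers(lo, hi + 1))

    epochs = pd.DataFrame(
        {
            "epoch_start": epoch_start[keep],
            "epoch_minutes": bin_minutes[keep],
            "steps": epoch_steps[keep],
        }
    )
    return StepStream(
        truth.participant_id, device_id or truth.device_id, epochs
    )


def sample_profiles(
    n: int,
    rng: np.random.Generator,
    *,
    median_daily_target: float = DEFAULT_DAILY_TARGET_MEDIAN,
    sigma: float = DEFAULT_DAILY_TARGET_SIGMA,
) -> list[ActivityProfile]:
    """Draw per-participant profiles with log-normal daily step targets."""
    targets = np.exp(rng.normal(math.log(median_daily_target), sigma, n))
    return [ActivityProfile(daily_total_target=float(t)) for t in targets]


def default_study_config(seed: int = 0) -> StudyConfig:
    """Study layout mirroring a four-tracker, 30-participant validation design.

    The reference is a minute-epoch research accelerometer recorded as the
    truth.  Tracker error parameters are set so systematic deficits sit in the
    low-thousands of steps per 72 h: a wrist smartwatch with a variable update
    interval and mild undercount, a 5-minute-epoch band with a larger
    undercount, a sparse-sync tracker that overcounts and exhibits the
    overnight carryover artifact, and a diary-style pedometer read once per
    day with occasional fully lost days.
    """
    devices = {
        "actigraph": DeviceErrorModel(),
        "smartwatch": DeviceErrorModel(
            update_interval="variable",
            variable_mean_minutes=9.25,
            undercount_fraction=0.044,
            epoch_noise_sd=15.0,
            battery_death_prob=0.10,
        ),
        "band5min": DeviceErrorModel(
            update_interval=5,
            undercount_fraction=0.092,
            epoch_noise_sd=5.0,
            malfunction_day_prob=0.033,
        ),
        "sparse_sync": DeviceErrorModel(
            update_interval="variable",
            variable_mean_minutes=130.0,
            undercount_fraction=-0.085,
            epoch_noise_sd=100.0,
            carryover_enabled=True,
            carryover_steps_range=(50, 500),
            malfunction_day_prob=0.022,
        ),
        "pedometer_diary": DeviceErrorModel(
            update_interval="daily",
            undercount_fraction=0.091,
            epoch_noise_sd=400.0,
            malfunction_day_prob=0.078,
        ),
    }
    return StudyConfig(seed=seed, device_models=devices, reference_device="actigraph")


def generate_study(config: StudyConfig) -> tuple[list[StepStream], pd.DataFrame]:
    """Simulate every stream of a study and build its manifest table.

    Returns the streams (reference plus one per tracker per participant) and a
    manifest DataFrame (participant_id, device_id, path, is_reference,
    n_epochs) whose paths are the filenames :func:`write_study` will use.
    Fully reproducible from ``config.seed``.
    """
    device_ids = list(config.device_models)
    if len(set(device_ids)) != len(device_ids):
        raise ValueError("duplicate device ids in device_models")
    root_ss = np.random.SeedSequence(config.seed)
    profile_ss, *participant_ss = root_ss.spawn(1 + config.n_participants)
    if config.profiles is not None:
        profiles = config.profiles
    else:
        profiles = sample_profiles(
            config.n_participants, np.random.default_rng(profile_ss)
        )

    streams: list[StepStream] = []
    manifest_rows = []
    t0 = pd.Timestamp(config.start)
    for i in range(config.n_participants):
        pid = participant_label(i)
        truth_ss, *device_ss = participant_ss[i].spawn(1 + len(device_ids))
        truth = generate_ground_truth(
            profiles[i],
            config.window_hours,
            truth_ss,
            participant_id=pid,
            start=t0,
        )
        truth = _apply_nonwear(truth, config.nonwear.get(pid, []))
        for dev, dev_ss in zip(device_ids, device_ss):
            obs = observe(truth, config.device_models[dev], dev_ss, device_id=dev)
            streams.append(obs)
            manifest_rows.append(
                {
                    "participant_id": pid,
                    "device_id": dev,
                    "path": f"{pid}_{dev}.csv",
                    "is_reference": dev == config.reference_device,
                    "n_epochs": len(obs),
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    return streams, manifest


def _apply_nonwear(
    truth: StepStream, intervals: list[tuple[str, str]]
) -> StepStream:
    """Zero the truth within explicit device-off intervals (all devices off)."""
    if not intervals:
        return truth
    epochs = truth.epochs.copy()
    for lo, hi in intervals:
        lo_t, hi_t = pd.Timestamp(lo), pd.Timestamp(hi)
        sel = (epochs["epoch_start"] >= lo_t) & (epochs["epoch_start"] < hi_t)
        epochs.loc[sel, "steps"] = 0
    return StepStream(truth.participant_id, truth.device_id, epochs)


def write_study(
    streams: list[StepStream], manifest: pd.DataFrame, out_dir
) -> str:
    """Write one CSV per stream plus ``manifest.csv``; returns the manifest path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    by_key = {(s.participant_id, s.device_id): s for s in streams}
    for row in manifest.itertuples(index=False):
        stream = by_key[(row.participant_id, row.device_id)]
        stream.to_frame().to_csv(os.path.join(out_dir, row.path), index=False)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def simulate_difference_study(
    n_pairs: int,
    diff_mean: float,
    diff_sd: float,
    rng: np.random.Generator,
    *,
    reference_median: float = 21_000.0,
    reference_sigma: float = 0.2,
    device_id: str = "sim",
) -> "PairedTotals":
    """Draw paired 72-h totals with an additive Normal difference.

    Reference totals are log-normal around ``reference_median``; the tracker
    total is reference minus a Normal(diff_mean, diff_sd) draw, floored at
    zero.  Used for parameter-recovery and bias-correction experiments where
    only the paired-total distribution matters, not the epoch machinery.
    """
    from .models import PairedTotals

    ref = np.exp(rng.normal(math.log(reference_median), reference_sigma, n_pairs))
    diffs = rng.normal(diff_mean, diff_sd, n_pairs)
    trk = np.maximum(ref - diffs, 0.0)
    pairs = pd.DataFrame(
        {
            "participant_id": [participant_label(i) for i in range(n_pairs)],
            "reference_steps": np.rint(ref).astype(np.int64),
            "tracker_steps": np.rint(trk).astype(np.int64),
        }
    )
    return PairedTotals(device_id, pairs)
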
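"""Core data containers shared across the pipeline.

A :class:`StepStream` is one device's step record for one participant: an
ordered, non-overlapping sequence of epochs, each with a start timestamp, a
duration in whole minutes and a nonnegative integer step count.  Epochs carry
no hidden state — the stream total is simply the sum of the epoch counts.

A :class:`WearMask` partitions a participant's analysis window into
alternating ``worn`` / ``nonworn`` intervals, derived from the reference
device.  :class:`PairedTotals` holds the per-participant (reference total,
tracker total) pairs on which the agreement statistics operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_COLUMNS = ["epoch_start", "epoch_minutes", "steps"]

STREAM_CSV_COLUMNS = [
    "participant_id",
    "device_id",
    "epoch_start_iso8601",
    "epoch_minutes",
    "steps",
]

MANIFEST_COLUMNS = ["participant_id", "device_id", "path", "is_reference"]

WORN = "worn"
NONWORN = "nonworn"


class StreamValidationError(ValueError):
    """A stream (or one of its rows) violates the epoch-record contract."""


class ResolutionError(ValueError):
    """An operation requires 1-minute epochs and the stream has coarser ones."""


class InsufficientDataError(ValueError):
    """Too few paired totals for the requested statistic."""


def _empty_epochs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epoch_start": pd.Series([], dtype="datetime64[ns]"),
            "epoch_minutes": pd.Series([], dtype="int64"),
            "steps": pd.Series([], dtype="int64"),
        }
    )


@dataclass
class StepStream:
    """Timestamped epoch step counts for one (participant, device) pair."""

    participant_id: str
    device_id: str
    epochs: pd.DataFrame = field(default_factory=_empty_epochs)

    def __post_init__(self) -> None:
        df = self.epochs
        missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
        if missing:
            raise StreamValidationError(
                f"stream {self.participant_id}/{self.device_id}: "
                f"missing epoch columns {missing}"
            )
        df = df[EPOCH_COLUMNS].copy()
        df["epoch_start"] = pd.to_datetime(df["epoch_start"])
        df["epoch_minutes"] = df["epoch_minutes"].astype("int64")
        df["steps"] = df["steps"].astype("int64")
        df = df.sort_values("epoch_start", kind="stable").reset_index(drop=True)
        if len(df):
            if (df["epoch_minutes"] < 1).any():
                row = int(df.index[df["epoch_minutes"] < 1][0])
                raise StreamValidationError(
                    f"stream {self.participant_id}/{self.device_id} row {row}: "
                    "epoch duration must be >= 1 minute"
                )
            if (df["steps"] < 0).any():
                row = int(df.index[df["steps"] < 0][0])
                raise StreamValidationError(
                    f"stream {self.participant_id}/{self.device_id} row {row}: "
                    "steps must be >= 0"
                )
            ends = df["epoch_start"] + pd.to_timedelta(df["epoch_minutes"], unit="m")
            overlap = ends.values[:-1] > df["epoch_start"].values[1:]
            if overlap.any():
                row = int(np.flatnonzero(overlap)[0])
                raise StreamValidationError(
                    f"stream {self.participant_id}/{self.device_id} row {row + 1}: "
                    "epochs overlap the preceding epoch"
                )
        self.epochs = df

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def total_steps(self) -> int:
        return int(self.epochs["steps"].sum())

    @property
    def start(self) -> pd.Timestamp | None:
        if not len(self.epochs):
            return None
        return self.epochs["epoch_start"].iloc[0]

    @property
    def end(self) -> pd.Timestamp | None:
        """End of the last epoch (half-open: the minute past the final record)."""
        if not len(self.epochs):
            return None
        last = self.epochs.iloc[-1]
        return last["epoch_start"] + pd.Timedelta(minutes=int(last["epoch_minutes"]))

    @property
    def is_minute_resolution(self) -> bool:
        return bool(len(self.epochs)) and bool((self.epochs["epoch_minutes"] == 1).all())

    def to_frame(self) -> pd.DataFrame:
        """Serialise to the interchange CSV schema (ISO-8601 timestamps)."""
        df = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "device_id": self.device_id,
                "epoch_start_iso8601": self.epochs["epoch_start"].dt.strftime(
                    "%Y-%m-%dT%H:%M:%S"
                ),
                "epoch_minutes": self.epochs["epoch_minutes"],
                "steps": self.epochs["steps"],
            }
        )
        return df

    def steps_within(self, window_start: pd.Timestamp, window_end: pd.Timestamp) -> int:
        """Total steps of epochs whose start lies in [window_start, window_end)."""
        sel = (self.epochs["epoch_start"] >= window_start) & (
            self.epochs["epoch_start"] < window_end
        )
        return int(self.epochs.loc[sel, "steps"].sum())


@dataclass
class WearMask:
    """Worn/nonworn partition of one participant's analysis window.

    ``intervals`` has columns ``start``, ``end`` (half-open timestamps) and
    ``status`` (``worn`` or ``nonworn``); the intervals are contiguous, cover
    the window exactly and alternate in status.
    """

    participant_id: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals[["start", "end", "status"]].copy()
        df["start"] = pd.to_datetime(df["start"])
        df["end"] = pd.to_datetime(df["end"])
        df = df.sort_values("start", kind="stable").reset_index(drop=True)
        if not len(df):
            raise StreamValidationError("wear mask must contain at least one interval")
        bad = ~df["status"].isin([WORN, NONWORN])
        if bad.any():
            raise StreamValidationError(f"invalid mask status {df.loc[bad, 'status'].iloc[0]!r}")
        if (df["end"] <= df["start"]).any():
            raise StreamValidationError("mask intervals must have positive duration")
        if len(df) > 1:
            if (df["start"].values[1:] != df["end"].values[:-1]).any():
                raise StreamValidationError("mask intervals must tile the window contiguously")
            same = df["status"].values[1:] == df["status"].values[:-1]
            if same.any():
                raise StreamValidationError("adjacent mask intervals must alternate status")
        self.intervals = df

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.intervals["start"].iloc[0], self.intervals["end"].iloc[-1]

    def worn_intervals(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        sel = self.intervals["status"] == WORN
        return list(
            zip(self.intervals.loc[sel, "start"], self.intervals.loc[sel, "end"])
        )

    @property
    def worn_minutes(self) -> int:
        sel = self.intervals["status"] == WORN
        dur = self.intervals.loc[sel, "end"] - self.intervals.loc[sel, "start"]
        return int(dur.sum() / pd.Timedelta(minutes=1))


@dataclass
class PairedTotals:
    """Per-participant (reference, tracker) step totals for one device.

    The MAD statistic divides by the reference total, so every retained pair
    must have ``reference_steps > 0``; participants without usable device data
    are absent rather than zero-filled.
    """

    device_id: str
    pairs: pd.DataFrame  # participant_id, reference_steps, tracker_steps

    def __post_init__(self) -> None:
        cols = ["participant_id", "reference_steps", "tracker_steps"]
        df = self.pairs[cols].copy().reset_index(drop=True)
        if df["participant_id"].duplicated().any():
            dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise StreamValidationError(
                f"device {self.device_id}: duplicate pair for participant {dup}"
            )
        if len(df) and (df["reference_steps"] <= 0).any():
            pid = df.loc[df["reference_steps"] <= 0, "participant_id"].iloc[0]
            raise StreamValidationError(
                f"device {self.device_id}: nonpositive reference total for {pid}"
            )
        self.pairs = df

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def reference(self) -> np.ndarray:
        return self.pairs["reference_steps"].to_numpy(dtype=float)

    @property
    def tracker(self) -> np.ndarray:
        return self.pairs["tracker_steps"].to_numpy(dtype=float)

    @property
    def differences(self) -> np.ndarray:
        """Reference minus tracker; positive means the tracker undercounts."""
        return self.reference - self.tracker
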
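"""Stream ingestion, reference-based nonwear removal, and pair aggregation.

Cleaning follows the usual actigraphy convention: wear status is decided on
the reference device alone — maximal runs of consecutive zero-step minutes at
least ``min_zero_run_minutes`` long (default 60) are nonwear — and the
resulting mask is excised from *every* device of that participant by
wall-clock interval, so both members of each pair are totalled over the same
worn time.  Tracker epochs that straddle a mask boundary lose steps in
proportion to the overlapped fraction (nearest-integer rounding), because the
within-epoch step placement is unknown.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .models import (
    MANIFEST_COLUMNS,
    NONWORN,
    STREAM_CSV_COLUMNS,
    WORN,
    PairedTotals,
    ResolutionError,
    StepStream,
    StreamValidationError,
    WearMask,
)

DEFAULT_NONWEAR_MIN_RUN = 60

# exclusion reasons written to exclusions.csv
REASON_NO_STREAM = "no data stream"
REASON_NO_REFERENCE = "no reference data"
REASON_REFERENCE_ZERO = "reference total is zero after cleaning"
REASON_NO_USABLE_DATA = "no usable data in analysis window"
REASON_TOO_FEW_PAIRS = "fewer than 2 usable pairs for device"


def read_manifest(manifest_path: str) -> pd.DataFrame:
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise StreamValidationError(f"manifest {manifest_path}: missing columns {missing}")
    return manifest


def read_streams(manifest_path: str) -> list[StepStream]:
    """Load and validate every stream listed in a manifest.

    Paths in the manifest are resolved relative to the manifest's directory.
    Malformed rows raise :class:`StreamValidationError` naming the file, row
    number, participant and device.
    """
    manifest = read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    streams = []
    for row in manifest.itertuples(index=False):
        path = os.path.join(base, row.path)
        if not os.path.exists(path):
            raise StreamValidationError(
                f"missing stream file {row.path} "
                f"(participant {row.participant_id}, device {row.device_id})"
            )
        streams.append(_read_stream_csv(path, str(row.participant_id), str(row.device_id)))
    return streams


def _read_stream_csv(path: str, participant_id: str, device_id: str) -> StepStream:
    df = pd.read_csv(path)
    missing = [c for c in STREAM_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise StreamValidationError(f"{path}: missing columns {missing}")
    # row-numbered diagnostics (header is line 1, first record line 2)
    for col, ok in [
        ("steps", df["steps"] >= 0),
        ("epoch_minutes", df["epoch_minutes"] >= 1),
    ]:
        bad = ~ok
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise StreamValidationError(
                f"{path} line {line} (participant {participant_id}, device "
                f"{device_id}): invalid {col} value {df.loc[bad, col].iloc[0]!r}"
            )
    epochs = pd.DataFrame(
        {
            "epoch_start": pd.to_datetime(df["epoch_start_iso8601"]),
            "epoch_minutes": df["epoch_minutes"],
            "steps": df["steps"],
        }
    )
    return StepStream(participant_id, device_id, epochs)


def detect_nonwear(
    reference: StepStream,
    min_zero_run_minutes: int = DEFAULT_NONWEAR_MIN_RUN,
) -> WearMask:
    """Mark maximal zero-step runs >= threshold on the reference as nonworn.

    The reference must be a contiguous 1-minute-epoch stream; a 59-minute run
    under the default threshold stays worn.
    """
    if min_zero_run_minutes < 1:
        raise ValueError("min_zero_run_minutes must be >= 1")
    if not reference.is_minute_resolution:
        raise ResolutionError(
            f"nonwear detection requires 1-minute reference epochs "
            f"(participant {reference.participant_id})"
        )
    starts = reference.epochs["epoch_start"]
    if len(starts) > 1:
        gaps = starts.diff().iloc[1:] != pd.Timedelta(minutes=1)
        if gaps.any():
            raise ResolutionError(
                f"reference stream for {reference.participant_id} has gaps; "
                "nonwear detection needs a contiguous minute grid"
            )
    steps = reference.epochs["steps"].to_numpy()
    zero = steps == 0
    # run-length encode the zero indicator
    change = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
    run_starts = np.concatenate(([0], change))
    run_ends = np.concatenate((change, [len(zero)]))
    t0 = starts.iloc[0]
    rows = []
    for a, b in zip(run_starts, run_ends):
        nonworn = bool(zero[a]) and (b - a) >= min_zero_run_minutes
        rows.append(
            {
                "start": t0 + pd.Timedelta(minutes=int(a)),
                "end": t0 + pd.Timedelta(minutes=int(b)),
                "status": NONWORN if nonworn else WORN,
            }
        )
    intervals = pd.DataFrame(rows)
    # merge adjacent intervals that ended up with the same status
    merged = [intervals.iloc[0].to_dict()]
    for _, row in intervals.iloc[1:].iterrows():
        if row["status"] == merged[-1]["status"]:
            merged[-1]["end"] = row["end"]
        else:
            merged.append(row.to_dict())
    return WearMask(reference.participant_id, pd.DataFrame(merged))


#: Epochs at least this long are treated as diary-style day records: the
#: once-per-day count already covers only worn time, so they are kept whole
#: (or dropped wholesale) rather than sub-day masked.
DIARY_MIN_EPOCH_MINUTES = 720


def mask_streams(
    streams: list[StepStream],
    mask: WearMask,
    *,
    diary_min_epoch_minutes: int = DIARY_MIN_EPOCH_MINUTES,
) -> list[StepStream]:
    """Excise the mask's nonworn time from every stream of the participant.

    Epochs fully nonworn are dropped; epochs partially overlapping worn time
    keep ``round(steps * worn_fraction)`` steps.  Epochs entirely outside the
    mask window are dropped (they fall outside the analysis window).
    Day-length diary epochs cannot be sub-day masked and are kept whole when
    they touch any worn time.
    """
    worn = mask.worn_intervals()
    out = []
    for stream in streams:
        if stream.participant_id != mask.participant_id:
            raise StreamValidationError(
                f"wear mask for {mask.participant_id} applied to stream of "
                f"{stream.participant_id}"
            )
        if not len(stream):
            out.append(stream)
            continue
        starts = stream.epochs["epoch_start"].to_numpy()
        minutes = stream.epochs["epoch_minutes"].to_numpy()
        ends = starts + minutes * np.timedelta64(60, "s")
        overlap = np.zeros(len(stream), dtype=float)
        for w_start, w_end in worn:
            lo = np.maximum(starts, np.datetime64(w_start))
            hi = np.minimum(ends, np.datetime64(w_end))
            overlap += np.maximum((hi - lo) / np.timedelta64(60, "s"), 0.0)
        frac = overlap / minutes
        diary = minutes >= diary_min_epoch_minutes
        frac[diary & (overlap > 0)] = 1.0
        steps = np.floor(stream.epochs["steps"].to_numpy() * frac + 0.5)
        keep = frac > 0
        epochs = pd.DataFrame(
            {
                "epoch_start": starts[keep],
                "epoch_minutes": minutes[keep],
                "steps": steps[keep].astype(np.int64),
            }
        )
        out.append(StepStream(stream.participant_id, stream.device_id, epochs))
    return out


def aggregate_pairs(
    streams: list[StepStream],
    reference_device: str,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    window_hours: float | None = None,
    windows: dict[str, tuple[pd.Timestamp, pd.Timestamp]] | None = None,
) -> tuple[dict[str, PairedTotals], pd.DataFrame]:
    """Total each device over the analysis window and pair with the reference.

    The window is given explicitly (``window`` globally, or ``windows`` per
    participant — typically the wear-mask coverage), or derived per
    participant as the reference stream's coverage truncated to
    ``window_hours``; a reference with missing trailing hours therefore
    shortens that participant's window.
    Pairs are dropped — with a recorded reason — when either member has no
    usable data or the reference total is zero.  Returns one
    :class:`PairedTotals` per tracker device plus the exclusions table.
    """
    by_participant: dict[str, dict[str, StepStream]] = {}
    device_ids: list[str] = []
    for s in streams:
        by_participant.setdefault(s.participant_id, {})[s.device_id] = s
        if s.device_id not in device_ids:
            device_ids.append(s.device_id)
    if reference_device not in device_ids:
        raise StreamValidationError(f"reference device {reference_device!r} absent from streams")
    trackers = [d for d in device_ids if d != reference_device]

    pair_rows: dict[str, list[dict]] = {d: [] for d in trackers}
    exclusions = []
    for pid in sorted(by_participant):
        devices = by_participant[pid]
        ref = devices.get(reference_device)
        if ref is None or not len(ref):
            for dev in trackers:
                exclusions.append(
                    {"participant_id": pid, "device_id": dev, "reason": REASON_NO_REFERENCE}
                )
            continue
        if windows is not None and pid in windows:
            w_start, w_end = windows[pid]
        elif window is not None:
            w_start, w_end = window
        else:
            w_start = ref.start
            w_end = ref.end
        if window_hours is not None:
            w_end = min(w_end, w_start + pd.Timedelta(hours=window_hours))
        ref_total = ref.steps_within(w_start, w_end)
        for dev in trackers:
            trk = devices.get(dev)
            if trk is None:
                exclusions.append(
                    {"participant_id": pid, "device_id": dev, "reason": REASON_NO_STREAM}
                )
                continue
            if ref_total <= 0:
                exclusions.append(
                    {"participant_id": pid, "device_id": dev, "reason": REASON_REFERENCE_ZERO}
                )
                continue
            in_window = (trk.epochs["epoch_start"] >= w_start) & (
                trk.epochs["epoch_start"] < w_end
            )
            if not len(trk) or not in_window.any():
                exclusions.append(
                    {"participant_id": pid, "device_id": dev, "reason": REASON_NO_USABLE_DATA}
                )
                continue
            pair_rows[dev].append(
                {
                    "participant_id": pid,
                    "reference_steps": ref_total,
                    "tracker_steps": trk.steps_within(w_start, w_end),
                }
            )

    paired: dict[str, PairedTotals] = {}
    for dev in trackers:
        rows = pair_rows[dev]
        if rows:
            paired[dev] = PairedTotals(dev, pd.DataFrame(rows))
        else:
            paired[dev] = PairedTotals(
                dev,
                pd.DataFrame(
                    columns=["participant_id", "reference_steps", "tracker_steps"]
                ),
            )
    exclusions_df = pd.DataFrame(
        exclusions, columns=["participant_id", "device_id", "reason"]
    )
    return paired, exclusions_df
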
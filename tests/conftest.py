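"""Shared fixtures: a fully hand-checkable 3-participant toy study.

The toy study is built from arithmetic patterns (10 reference steps per
waking minute, 9 or 10 tracker steps per minute in 5-minute epochs) so every
downstream number — masked totals, pairs, exclusions, agreement statistics —
can be computed by hand and frozen in the tests.

Layout (72 h from 2016-06-06 00:00, waking window 08:00-22:00):

* ``actigraph`` (reference, 1-min epochs): 10 steps per waking minute.
  Participant p01 additionally has a 90-minute zero run 10:00-11:30 on day 1.
* ``trk`` (5-min epochs, 45 steps per waking epoch = 10% undercount):
  participant p02 loses all of day 2.
* ``trk2`` (5-min epochs, 50 steps per waking epoch = identity): only
  p01 and p03 have this device, so p02 yields an exclusion row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stepagree import StepStream
from stepagree.synthetic import write_study

T0 = pd.Timestamp("2016-06-06 00:00:00")
WAKING = (8, 22)


def _reference_steps(n_min: int, zero_run: tuple[int, int] | None = None) -> np.ndarray:
    minutes = T0 + pd.to_timedelta(np.arange(n_min), unit="m")
    waking = (minutes.hour >= WAKING[0]) & (minutes.hour < WAKING[1])
    steps = np.where(waking, 10, 0)
    if zero_run is not None:
        steps[zero_run[0] : zero_run[1]] = 0
    return steps


def minute_stream(
    pid: str, dev: str, steps: np.ndarray
) -> StepStream:
    minutes = T0 + pd.to_timedelta(np.arange(len(steps)), unit="m")
    return StepStream(
        pid, dev, pd.DataFrame({"epoch_start": minutes, "epoch_minutes": 1, "steps": steps})
    )


def five_minute_stream(
    pid: str, dev: str, minute_steps: np.ndarray, drop_day: int | None = None
) -> StepStream:
    n_bins = len(minute_steps) // 5
    steps = minute_steps[: n_bins * 5].reshape(n_bins, 5).sum(axis=1)
    starts = T0 + pd.to_timedelta(np.arange(n_bins) * 5, unit="m")
    epochs = pd.DataFrame({"epoch_start": starts, "epoch_minutes": 5, "steps": steps})
    if drop_day is not None:
        day = ((epochs["epoch_start"] - T0) // pd.Timedelta(days=1)).astype(int)
        epochs = epochs[day != drop_day]
    return StepStream(pid, dev, epochs)


def build_toy_streams() -> list[StepStream]:
    n_min = 72 * 60
    # p01: 90-minute zero run on day 1, 10:00-11:30
    zero_run = (10 * 60, 11 * 60 + 30)
    streams = []
    for pid, ref_zero in [("p01", zero_run), ("p02", None), ("p03", None)]:
        ref_steps = _reference_steps(n_min, ref_zero)
        streams.append(minute_stream(pid, "actigraph", ref_steps))
        trk_minutes = (ref_steps * 9) // 10  # exact: 10 -> 9, 0 -> 0
        streams.append(
            five_minute_stream(
                pid, "trk", trk_minutes, drop_day=1 if pid == "p02" else None
            )
        )
        if pid != "p02":
            streams.append(five_minute_stream(pid, "trk2", ref_steps))
    return streams


@pytest.fixture()
def toy_study_dir(tmp_path):
    """Write the toy study to disk; returns the manifest path."""
    streams = build_toy_streams()
    manifest = pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "device_id": s.device_id,
                "path": f"{s.participant_id}_{s.device_id}.csv",
                "is_reference": s.device_id == "actigraph",
                "n_epochs": len(s),
            }
            for s in streams
        ]
    )
    return write_study(streams, manifest, tmp_path / "toy")
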
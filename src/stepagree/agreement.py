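"""Agreement statistics for paired step totals.

Three statistics summarise how a tracker agrees with the reference over the
analysis window:

* **Bland-Altman** — bias = mean(reference − tracker), sample SD of the
  differences (n−1 denominator) and 95% limits of agreement
  LoA = bias ± 1.96 × SD.  With this sign convention a positive bias means
  the tracker undercounts on average.
* **MAD%** — the median over participants of
  ``|tracker − reference| / reference``, as a percentage.  A robust accuracy
  measure for skewed step data; ≤15% is the usual clinical acceptability cut.
* **LOOCV-corrected MAD%** — for each held-out participant the bias is
  re-estimated on the remaining n−1 pairs and added to that participant's
  tracker total; the MAD of the corrected pairs estimates the accuracy
  achievable after correcting the device's systematic offset, without using
  any participant's own data in their correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .models import InsufficientDataError, PairedTotals

LOA_MULTIPLIER = 1.96
MAD_ACCEPTABLE_PERCENT = 15.0


@dataclass
class AgreementSummary:
    """Agreement of one tracker with the reference."""

    device_id: str
    n_pairs: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    mad_percent: Optional[float] = None
    mad_corrected_percent: Optional[float] = None
    per_fold_bias: Optional[list[float]] = None
    loa_multiplier: float = LOA_MULTIPLIER

    def rounded(self) -> dict:
        """Table-style rounding: whole steps, MAD to one decimal percent."""
        out = {
            "device_id": self.device_id,
            "n_pairs": self.n_pairs,
            "mad_percent": None if self.mad_percent is None else round(self.mad_percent, 1),
            "sd": int(np.rint(self.sd)),
            "bias": int(np.rint(self.bias)),
            "loa_low": int(np.rint(self.loa_low)),
            "loa_high": int(np.rint(self.loa_high)),
            "mad_corrected_percent": (
                None
                if self.mad_corrected_percent is None
                else round(self.mad_corrected_percent, 1)
            ),
        }
        return out


@dataclass
class BlandAltmanPoint:
    participant_id: str
    mean_steps: float
    diff_steps: float


def limits_of_agreement(
    bias: float, sd: float, multiplier: float = LOA_MULTIPLIER
) -> tuple[float, float]:
    """LoA = bias ± multiplier × SD (multiplier fixed at 1.96 by default)."""
    return bias - multiplier * sd, bias + multiplier * sd


def bland_altman(
    pairs: PairedTotals, multiplier: float = LOA_MULTIPLIER
) -> AgreementSummary:
    """Bias, SD of differences, and 95% limits of agreement."""
    n = len(pairs)
    if n < 2:
        raise InsufficientDataError(
            f"device {pairs.device_id}: Bland-Altman needs >= 2 pairs, got {n}"
        )
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = limits_of_agreement(bias, sd, multiplier)
    return AgreementSummary(
        device_id=pairs.device_id,
        n_pairs=n,
        bias=bias,
        sd=sd,
        loa_low=lo,
        loa_high=hi,
        loa_multiplier=multiplier,
    )


def mad(pairs: PairedTotals) -> float:
    """Median absolute relative difference, in percent.

    ``median(|tracker - reference| / reference) * 100``; an even number of
    pairs uses the mean of the two central order statistics.
    """
    if len(pairs) < 1:
        raise InsufficientDataError(f"device {pairs.device_id}: no pairs for MAD")
    ref = pairs.reference
    if np.any(ref <= 0):
        raise InsufficientDataError(
            f"device {pairs.device_id}: MAD undefined for nonpositive reference totals"
        )
    rel = np.abs(pairs.tracker - ref) / ref
    return float(np.median(rel) * 100.0)


def loocv_bias_correction(
    pairs: PairedTotals,
    correction: Literal["additive", "proportional"] = "additive",
) -> tuple[float, list[float]]:
    """Leave-one-out cross-validated bias-corrected MAD.

    For each pair i the correction is fit on the other n−1 pairs and applied
    to pair i's tracker total: additively (tracker + training bias, the
    default, matching the Bland-Altman bias definition) or proportionally
    (tracker × training mean-ratio).  Returns the corrected MAD% and the
    per-fold training biases (or ratios) for audit.
    """
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(
            f"device {pairs.device_id}: LOOCV needs >= 3 pairs, got {n}"
        )
    ref = pairs.reference
    trk = pairs.tracker
    d = ref - trk
    corrected = np.empty(n)
    per_fold = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if correction == "additive":
            b = float(np.mean(d[train]))
            corrected[i] = trk[i] + b
        elif correction == "proportional":
            b = float(np.sum(ref[train]) / np.sum(trk[train]))
            corrected[i] = trk[i] * b
        else:
            raise ValueError(f"unknown correction {correction!r}")
        per_fold.append(b)
    rel = np.abs(corrected - ref) / ref
    return float(np.median(rel) * 100.0), per_fold


def ba_plot_data(
    pairs: PairedTotals, multiplier: float = LOA_MULTIPLIER
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Points and reference lines of the Bland-Altman plot.

    Returns one (mean, difference) point per pair and the three horizontal
    reference values (bias and both limits of agreement), which equal the
    :func:`bland_altman` outputs exactly.
    """
    summary = bland_altman(pairs, multiplier)
    points = pd.DataFrame(
        {
            "participant_id": pairs.pairs["participant_id"],
            "mean_steps": (pairs.reference + pairs.tracker) / 2.0,
            "diff_steps": pairs.differences,
        }
    )
    lines = {
        "bias": summary.bias,
        "loa_low": summary.loa_low,
        "loa_high": summary.loa_high,
    }
    return points, lines


def summarize(
    pairs: PairedTotals,
    multiplier: float = LOA_MULTIPLIER,
    correction: Literal["additive", "proportional"] = "additive",
) -> AgreementSummary:
    """Full agreement summary; the LOOCV field is left empty when n < 3."""
    summary = bland_altman(pairs, multiplier)
    summary.mad_percent = mad(pairs)
    if len(pairs) >= 3:
        corrected, per_fold = loocv_bias_correction(pairs, correction)
        summary.mad_corrected_percent = corrected
        summary.per_fold_bias = per_fold
    return summary
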
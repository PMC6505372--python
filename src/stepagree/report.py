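"""End-to-end validation runs and their serialized reports.

``run_validate`` chains the pipeline — read streams, derive the wear mask
from each participant's reference, excise nonwear from all paired devices,
aggregate to per-participant totals, compute agreement statistics — and
writes a stable set of artifacts: ``summary.csv`` / ``summary.json``,
``paired_totals.csv``, ``ba_points_<device>.csv``, ``exclusions.csv`` and
``wear_mask.csv``.  Output is deterministic for fixed inputs and options
(sorted JSON keys, fixed formatting), and the report carries a config hash
over the inputs and options so a run can be tied to exactly what produced it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .agreement import (
    LOA_MULTIPLIER,
    MAD_ACCEPTABLE_PERCENT,
    AgreementSummary,
    ba_plot_data,
    summarize,
)
from .ingest import (
    DEFAULT_NONWEAR_MIN_RUN,
    REASON_TOO_FEW_PAIRS,
    aggregate_pairs,
    detect_nonwear,
    mask_streams,
    read_manifest,
    read_streams,
)
from .models import PairedTotals, StreamValidationError
from .synthetic import StudyConfig, generate_study, write_study


@dataclass
class ValidationReport:
    metadata: dict
    summaries: dict[str, AgreementSummary]
    paired: dict[str, PairedTotals]
    exclusions: pd.DataFrame
    wear_masks: pd.DataFrame
    config_hash: str = ""
    version: str = field(default=__version__)


def _hash_inputs(manifest_path: str, options: dict) -> str:
    h = hashlib.sha256()
    base = os.path.dirname(os.path.abspath(manifest_path))
    with open(manifest_path, "rb") as fh:
        h.update(fh.read())
    manifest = read_manifest(manifest_path)
    for path in sorted(manifest["path"]):
        with open(os.path.join(base, path), "rb") as fh:
            h.update(fh.read())
    h.update(json.dumps(options, sort_keys=True).encode())
    return h.hexdigest()


def run_validate(
    manifest_path: str,
    out_dir: str | None = None,
    *,
    nonwear_min_run: int = DEFAULT_NONWEAR_MIN_RUN,
    window_hours: float = 72.0,
    correction: str = "additive",
    loa_multiplier: float = LOA_MULTIPLIER,
    mad_threshold: float = MAD_ACCEPTABLE_PERCENT,
) -> ValidationReport:
    """Run the cleaning + agreement pipeline on a study manifest.

    Every device in the manifest ends up either in the summaries or in the
    exclusions table; devices with fewer than 2 usable pairs cannot be
    summarised and are excluded wholesale.
    """
    options = {
        "nonwear_min_run": nonwear_min_run,
        "window_hours": window_hours,
        "correction": correction,
        "loa_multiplier": loa_multiplier,
        "mad_threshold": mad_threshold,
    }
    manifest = read_manifest(manifest_path)
    ref_devices = manifest.loc[manifest["is_reference"], "device_id"].unique()
    if len(ref_devices) != 1:
        raise StreamValidationError(
            f"manifest must designate exactly one reference device, found {list(ref_devices)}"
        )
    reference_device = str(ref_devices[0])
    streams = read_streams(manifest_path)

    by_participant: dict[str, list] = {}
    for s in streams:
        by_participant.setdefault(s.participant_id, []).append(s)

    masked_streams = []
    mask_rows = []
    windows: dict[str, tuple] = {}
    for pid in sorted(by_participant):
        group = by_participant[pid]
        ref = next((s for s in group if s.device_id == reference_device), None)
        if ref is None or not len(ref):
            masked_streams.extend(group)  # aggregate_pairs will exclude them
            continue
        mask = detect_nonwear(ref, nonwear_min_run)
        windows[pid] = mask.window  # full recorded coverage, pre-masking
        masked_streams.extend(mask_streams(group, mask))
        for row in mask.intervals.itertuples(index=False):
            mask_rows.append(
                {
                    "participant_id": pid,
                    "start": row.start.strftime("%Y-%m-%dT%H:%M:%S"),
                    "end": row.end.strftime("%Y-%m-%dT%H:%M:%S"),
                    "status": row.status,
                }
            )

    paired, exclusions = aggregate_pairs(
        masked_streams, reference_device, window_hours=window_hours, windows=windows
    )

    summaries: dict[str, AgreementSummary] = {}
    extra_exclusions = []
    for dev in sorted(paired):
        if len(paired[dev]) < 2:
            extra_exclusions.append(
                {"participant_id": "*", "device_id": dev, "reason": REASON_TOO_FEW_PAIRS}
            )
            continue
        summaries[dev] = summarize(
            paired[dev], multiplier=loa_multiplier, correction=correction
        )
    if extra_exclusions:
        exclusions = pd.concat(
            [exclusions, pd.DataFrame(extra_exclusions)], ignore_index=True
        )

    if not summaries and exclusions.empty:
        raise StreamValidationError("no usable device pairs in study")

    metadata = {
        "n_participants": int(manifest["participant_id"].nunique()),
        "reference_device": reference_device,
        **options,
    }
    report = ValidationReport(
        metadata=metadata,
        summaries=summaries,
        paired=paired,
        exclusions=exclusions,
        wear_masks=pd.DataFrame(
            mask_rows, columns=["participant_id", "start", "end", "status"]
        ),
        config_hash=_hash_inputs(manifest_path, options),
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def report_to_json_dict(report: ValidationReport) -> dict:
    devices = {}
    for dev, s in report.summaries.items():
        devices[dev] = {
            "n_pairs": s.n_pairs,
            "bias": s.bias,
            "sd": s.sd,
            "loa_low": s.loa_low,
            "loa_high": s.loa_high,
            "mad_percent": s.mad_percent,
            "mad_corrected_percent": s.mad_corrected_percent,
            "per_fold_bias": s.per_fold_bias,
            "mad_acceptable": (
                None
                if s.mad_percent is None
                else bool(s.mad_percent <= report.metadata["mad_threshold"])
            ),
            "mad_corrected_acceptable": (
                None
                if s.mad_corrected_percent is None
                else bool(s.mad_corrected_percent <= report.metadata["mad_threshold"])
            ),
        }
    return {
        "version": report.version,
        "config_hash": report.config_hash,
        "metadata": report.metadata,
        "devices": devices,
        "exclusions": report.exclusions.to_dict(orient="records"),
    }


def write_report(report: ValidationReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    rows = [report.summaries[dev].rounded() for dev in sorted(report.summaries)]
    summary_df = pd.DataFrame(
        rows,
        columns=[
            "device_id",
            "n_pairs",
            "mad_percent",
            "sd",
            "bias",
            "loa_low",
            "loa_high",
            "mad_corrected_percent",
        ],
    )
    summary_df.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(report_to_json_dict(report), fh, sort_keys=True, indent=2)
        fh.write("\n")
    pair_frames = []
    for dev in sorted(report.paired):
        pairs = report.paired[dev]
        if len(pairs):
            frame = pairs.pairs.copy()
            frame.insert(0, "device_id", dev)
            pair_frames.append(frame)
    paired_df = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(
            columns=["device_id", "participant_id", "reference_steps", "tracker_steps"]
        )
    )
    paired_df.to_csv(os.path.join(out_dir, "paired_totals.csv"), index=False)
    report.exclusions.to_csv(os.path.join(out_dir, "exclusions.csv"), index=False)
    report.wear_masks.to_csv(os.path.join(out_dir, "wear_mask.csv"), index=False)
    for dev, summary in sorted(report.summaries.items()):
        points, lines = ba_plot_data(
            report.paired[dev], multiplier=summary.loa_multiplier
        )
        points = points.copy()
        for key, value in lines.items():
            points[key] = value
        points.to_csv(os.path.join(out_dir, f"ba_points_{dev}.csv"), index=False)


def run_simulate(config: StudyConfig, out_dir: str) -> str:
    """Generate a synthetic study and write its streams; returns the manifest path."""
    streams, manifest = generate_study(config)
    manifest_path = write_study(streams, manifest, out_dir)
    with open(os.path.join(out_dir, "study_config.json"), "w") as fh:
        fh.write(config.model_dump_json(indent=2))
        fh.write("\n")
    return manifest_path


def render_plots(out_dir: str) -> list[str]:
    """Render Bland-Altman PNGs from the ba_points CSVs in a report directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for name in sorted(os.listdir(out_dir)):
        if not (name.startswith("ba_points_") and name.endswith(".csv")):
            continue
        dev = name[len("ba_points_") : -len(".csv")]
        points = pd.read_csv(os.path.join(out_dir, name))
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(points["mean_steps"], points["diff_steps"], s=20)
        for key, style in [("bias", "-"), ("loa_low", "--"), ("loa_high", "--")]:
            ax.axhline(points[key].iloc[0], linestyle=style, color="gray")
        ax.set_xlabel("Mean of reference and tracker (steps)")
        ax.set_ylabel("Reference − tracker (steps)")
        ax.set_title(f"Bland-Altman: {dev} vs reference")
        path = os.path.join(out_dir, f"ba_plot_{dev}.png")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
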
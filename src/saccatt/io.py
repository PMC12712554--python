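"""Persistence: HDF5 trial records, CSV summaries, JSON run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .analysis import AnalysisSummary, ChangePointResult
from .experiment import TrialConfig, TrialRecord
from .network import LesionConfig
from .params import ParameterSet
from .signals import BarStimulus, EyeTrajectory

__all__ = [
    "save_records",
    "load_records",
    "bars_to_frame",
    "bars_from_frame",
    "save_summary_csv",
    "write_manifest",
]


def bars_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Bar streams as a tidy table (trial, x_deg, y_deg, onset_ms, duration_ms, side)."""
    rows = [
        {
            "trial": i,
            "x_deg": b.x_deg,
            "y_deg": b.y_deg,
            "onset_ms": b.onset,
            "duration_ms": b.duration,
            "side": b.side,
        }
        for i, rec in enumerate(records)
        for b in rec.bars
    ]
    return pd.DataFrame(rows, columns=["trial", "x_deg", "y_deg", "onset_ms", "duration_ms", "side"])


def bars_from_frame(frame: pd.DataFrame) -> dict[int, list[BarStimulus]]:
    """Inverse of :func:`bars_to_frame`, grouped by trial index."""
    out: dict[int, list[BarStimulus]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(int(row.trial), []).append(
            BarStimulus(
                x_deg=float(row.x_deg),
                y_deg=float(row.y_deg),
                onset=float(row.onset_ms),
                duration=float(row.duration_ms),
                side=str(row.side),
            )
        )
    return out


def save_records(path: str | Path, records: list[TrialRecord]) -> None:
    """Write trial records to an HDF5 file (one group per trial)."""
    with h5py.File(path, "w") as fh:
        for i, rec in enumerate(records):
            g = fh.create_group(f"trial{i:05d}")
            c = rec.config
            g.attrs["ap_index"] = c.ap_index
            g.attrs["mode"] = c.mode
            g.attrs["turnoff_time"] = np.nan if c.turnoff_time is None else c.turnoff_time
            g.attrs["seed"] = c.seed
            g.attrs["fef_to_v4_enabled"] = c.lesions.fef_to_v4_enabled
            g.attrs["lip_to_v4_enabled"] = c.lesions.lip_to_v4_enabled
            t = rec.trajectory
            g.attrs["fp"] = t.fp
            g.attrs["st"] = t.st
            g.attrs["saccade_onset"] = t.saccade_onset
            g.attrs["saccade_duration"] = t.saccade_duration
            g.attrs["row_y"] = rec.row_y
            bars = np.array(
                [(b.x_deg, b.y_deg, b.onset, b.duration, 1 if b.side == "above" else 0) for b in rec.bars],
                dtype=np.float64,
            ).reshape(-1, 5)
            g.create_dataset("bars", data=bars)
            if rec.v4_rows is not None:
                g.create_dataset("v4_rows", data=rec.v4_rows, compression="gzip", compression_opts=1)
            if rec.v4_full is not None:
                g.create_dataset("v4_full", data=rec.v4_full, compression="gzip", compression_opts=1)
            if rec.lip_rows is not None:
                g.create_dataset("lip_rows", data=rec.lip_rows, compression="gzip", compression_opts=1)


def load_records(path: str | Path) -> list[TrialRecord]:
    """Read trial records back from :func:`save_records` output."""
    records = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            turnoff = g.attrs["turnoff_time"]
            cfg = TrialConfig(
                ap_index=int(g.attrs["ap_index"]),
                mode=str(g.attrs["mode"]),
                turnoff_time=None if np.isnan(turnoff) else float(turnoff),
                seed=int(g.attrs["seed"]),
                lesions=LesionConfig(
                    fef_to_v4_enabled=bool(g.attrs["fef_to_v4_enabled"]),
                    lip_to_v4_enabled=bool(g.attrs["lip_to_v4_enabled"]),
                ),
            )
            traj = EyeTrajectory(
                fp=tuple(g.attrs["fp"]),
                st=tuple(g.attrs["st"]),
                saccade_onset=float(g.attrs["saccade_onset"]),
                saccade_duration=float(g.attrs["saccade_duration"]),
            )
            bars = [
                BarStimulus(
                    x_deg=float(r[0]),
                    y_deg=float(r[1]),
                    onset=float(r[2]),
                    duration=float(r[3]),
                    side="above" if r[4] > 0.5 else "below",
                )
                for r in g["bars"][()]
            ]
            records.append(
                TrialRecord(
                    config=cfg,
                    bars=bars,
                    trajectory=traj,
                    v4_rows=g["v4_rows"][()] if "v4_rows" in g else None,
                    row_y=tuple(g.attrs["row_y"]),
                    v4_full=g["v4_full"][()] if "v4_full" in g else None,
                    lip_rows=g["lip_rows"][()] if "lip_rows" in g else None,
                )
            )
    return records


def save_summary_csv(summary: AnalysisSummary, out_dir: str | Path) -> tuple[Path, Path]:
    """Write condition/normalized curves and detected change points as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for curve, pvals in (
        (summary.au, None),
        (summary.ua, None),
        (summary.uu, None),
        (summary.au_norm, summary.offset_au.p_values),
        (summary.ua_norm, summary.onset_ua.p_values),
    ):
        df = pd.DataFrame(
            {
                "condition": curve.condition,
                "bin_start_ms": curve.bin_starts,
                "mean": curve.mean,
                "sd": curve.sd,
                "n": curve.n,
            }
        )
        df["p"] = pvals if pvals is not None else np.nan
        frames.append(df)
    curves_path = out_dir / "curves.csv"
    pd.concat(frames, ignore_index=True).to_csv(curves_path, index=False)

    cps = pd.DataFrame(
        [
            {"kind": cp.kind, "time_ms": "" if cp.time_ms is None else cp.time_ms}
            for cp in (summary.offset_au, summary.onset_ua)
        ]
    )
    cps_path = out_dir / "changepoints.csv"
    cps.to_csv(cps_path, index=False)
    return curves_path, cps_path


def write_manifest(
    out_dir: str | Path,
    params: ParameterSet,
    seed: int,
    stage_outputs: dict[str, str],
    extra: dict | None = None,
) -> Path:
    """Write a JSON run manifest sufficient to re-run the stage."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "params": params.to_dict(),
        "params_digest": params.digest(),
        "outputs": stage_outputs,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
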
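"""Synthetic trial records with planted modulation profiles.

These records bypass the network entirely: probe-bar responses are
written directly into the V4 rate history with prescribed AU/UA
enhancement time courses and additive noise.  They exercise the analysis
layer (reverse correlation, normalization, change-point detection) in
isolation, with known ground truth.
"""

from __future__ import annotations

import numpy as np

from .experiment import FP, ST, TrialConfig, TrialRecord, _trial_seed, ap_position, classify_condition
from .geometry import FieldGeometry
from .params import ParameterSet
from .signals import generate_bar_stream, make_eye_trajectory

__all__ = ["FIXTURE_KINDS", "make_fixture_records"]

FIXTURE_KINDS = ("remap+linger", "remap-only", "null")


def make_fixture_records(
    kind: str,
    seed: int,
    n_trials: int = 60,
    params: ParameterSet | None = None,
    geometry: FieldGeometry | None = None,
    *,
    au_offset_ms: float | None = None,
    ua_onset_ms: float | None = None,
    baseline: float = 0.25,
    enhancement: float = 0.5,
    noise_sd: float = 0.05,
) -> list[TrialRecord]:
    """Generate records with a planted attentional-modulation structure.

    ``remap+linger`` plants a UA onset at −100 ms and an AU offset at
    +200 ms (the tonic-attention signature); ``remap-only`` keeps the UA
    onset but moves the AU offset to −20 ms; ``null`` plants no
    modulation anywhere.  Explicit change points override the defaults.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    params = params or ParameterSet()
    geometry = geometry or FieldGeometry()
    if kind == "null":
        au_off, ua_on = None, None
    else:
        au_off = au_offset_ms if au_offset_ms is not None else (200.0 if kind == "remap+linger" else -20.0)
        ua_on = ua_onset_ms if ua_onset_ms is not None else -100.0

    trajectory = make_eye_trajectory(FP, ST, params.saccade_onset, geometry, params)
    ap = ap_position(0, params)
    ap_control = (ap[0], -ap[1])
    row_y = (params.ap_offset_deg, -params.ap_offset_deg)
    n_steps = int(round(params.trial_duration / params.dt))
    window = int(round(20.0 / params.dt))
    rng = np.random.default_rng(seed)
    half_w = geometry.width_deg / 2

    records = []
    for i in range(n_trials):
        cfg = TrialConfig(ap_index=0, seed=_trial_seed(seed, i))
        bars = generate_bar_stream(geometry, trajectory, cfg.seed, params)
        rows = np.zeros((n_steps, 2, geometry.nx), dtype=np.float32)
        for b in bars:
            ex, ey = trajectory.position(b.onset)
            rx, ry = b.x_deg - ex, b.y_deg - ey
            if abs(rx) > half_w:
                continue
            iy, ix = geometry.to_index(rx, ry)
            x_node, y_node = geometry.to_deg(iy, ix)
            label = classify_condition((x_node, y_node), trajectory.vector, ap, ap_control, params.rf_tolerance_deg)
            onset_rel = b.onset - trajectory.saccade_onset
            active = 0.0
            if label == "AU" and au_off is not None and onset_rel < au_off:
                active = 1.0
            elif label == "UA" and ua_on is not None and onset_rel >= ua_on:
                active = 1.0
            amp = baseline * (1.0 + enhancement * active) + rng.normal(0.0, noise_sd)
            s0 = int(round(b.onset / params.dt))
            row = 0 if y_node >= 0 else 1
            seg = rows[s0 : s0 + window, row, ix]
            np.maximum(seg, max(amp, 0.0), out=seg)
        records.append(
            TrialRecord(config=cfg, bars=bars, trajectory=trajectory, v4_rows=rows, row_y=row_y)
        )
    return records
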
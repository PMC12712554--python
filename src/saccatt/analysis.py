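"""Measurement pipeline: reverse correlation and change-point detection.

The state of attention in model V4 is mapped with the probe bars: each
bar's response is the mean rate, over a 20 ms window from bar onset, of
the V4 Layer-4 neuron at the bar's retinotopic locus.  Responses are
pooled per condition (AU / UA / UU), binned by bar onset relative to
saccade onset (20 ms bins), the UU control is subtracted from AU and UA
(normalized activity), and the attentional change points are detected
with a three-consecutive-window significance rule: per bin a one-sided
one-sample t-test of the normalized responses against zero (p < 0.05,
trials as sampling unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .experiment import TrialRecord, ap_position, classify_condition
from .geometry import FieldGeometry
from .params import ParameterSet

__all__ = [
    "ProbeResponse",
    "ConditionCurve",
    "ChangePointResult",
    "AnalysisSummary",
    "RESPONSE_WINDOW_MS",
    "BIN_MS",
    "ALPHA",
    "reverse_correlate",
    "build_condition_curves",
    "normalize_curves",
    "detect_change",
    "visual_noise_floor",
    "analyze_records",
]

RESPONSE_WINDOW_MS = 20.0
BIN_MS = 20.0
ALPHA = 0.05
RUN_LENGTH = 3  # consecutive windows required by the detection rule


@dataclass(frozen=True)
class ProbeResponse:
    """Mean response of one neuron to one probe bar."""

    trial_index: int
    condition: str  # AU | UA | UU | none
    onset_rel: float  # bar onset, ms relative to saccade onset
    locus: tuple[float, float]  # responding neuron, retinotopic degrees
    response: float


@dataclass
class ConditionCurve:
    """Across-trial response curve of one condition in 20 ms onset bins."""

    condition: str
    bin_starts: np.ndarray  # ms relative to saccade onset
    samples: list[np.ndarray]  # per-bin response samples
    #: for normalized curves: the control condition's per-bin samples,
    #: centered on zero, so significance tests can account for the
    #: control's own sampling uncertainty
    ref_samples: list[np.ndarray] | None = None

    @property
    def mean(self) -> np.ndarray:
        return np.array([s.mean() if s.size else np.nan for s in self.samples])

    @property
    def sd(self) -> np.ndarray:
        return np.array([s.std(ddof=1) if s.size > 1 else np.nan for s in self.samples])

    @property
    def n(self) -> np.ndarray:
        return np.array([s.size for s in self.samples])


@dataclass(frozen=True)
class ChangePointResult:
    """Detected change point of attentional modulation.

    ``time_ms`` is the start of the first bin opening a run of three
    consecutive qualifying windows, relative to saccade onset, or ``None``
    if no qualifying run exists.
    """

    kind: str  # "offset-in-AU" | "onset-in-UA"
    time_ms: float | None
    p_values: np.ndarray
    bin_starts: np.ndarray


@dataclass
class AnalysisSummary:
    au: ConditionCurve
    ua: ConditionCurve
    uu: ConditionCurve
    au_norm: ConditionCurve
    ua_norm: ConditionCurve
    offset_au: ChangePointResult
    onset_ua: ChangePointResult


# ---------------------------------------------------------------------- #
def reverse_correlate(
    records: list[TrialRecord],
    params: ParameterSet | None = None,
    geometry: FieldGeometry | None = None,
) -> list[ProbeResponse]:
    """One response per (bar event, responding neuron) pair.

    The responding neuron is the V4 L4 neuron at the bar's retinotopic
    locus at bar onset; its response is the mean rate over the 20 ms
    window starting at bar onset.  Bars whose locus falls outside the
    field are skipped.  Each response is labelled with the neuron's
    AU/UA/UU condition for its trial.
    """
    params = params or ParameterSet()
    geometry = geometry or FieldGeometry()
    window = int(round(RESPONSE_WINDOW_MS / params.dt))
    half_w = geometry.width_deg / 2
    out: list[ProbeResponse] = []
    for idx, rec in enumerate(records):
        traj = rec.trajectory
        sacc_vec = traj.vector
        ap = ap_position(rec.config.ap_index, params)
        ap_control = (ap[0], -ap[1])
        for b in rec.bars:
            ex, ey = traj.position(b.onset)
            rx, ry = b.x_deg - ex, b.y_deg - ey
            if abs(rx) > half_w:
                continue  # locus outside the retinotopic field
            iy, ix = geometry.to_index(rx, ry)
            x_node, y_node = geometry.to_deg(iy, ix)
            s0 = max(0, int(round(b.onset / params.dt)))
            s1 = s0 + window
            if rec.v4_full is not None:
                trace = rec.v4_full[s0:s1, iy, ix]
            elif rec.v4_rows is not None:
                row = int(np.argmin([abs(y_node - y) for y in rec.row_y]))
                trace = rec.v4_rows[s0:s1, row, ix]
            else:
                raise ValueError("record carries no V4 rate history")
            if trace.size == 0:
                continue
            label = classify_condition((x_node, y_node), sacc_vec, ap, ap_control, params.rf_tolerance_deg)
            out.append(
                ProbeResponse(
                    trial_index=idx,
                    condition=label,
                    onset_rel=b.onset - traj.saccade_onset,
                    locus=(x_node, y_node),
                    response=float(trace.mean()),
                )
            )
    return out


def _bin_edges(params: ParameterSet) -> np.ndarray:
    w = params.bar_window
    return np.arange(-w, w + BIN_MS / 2, BIN_MS)


def build_condition_curves(
    responses: list[ProbeResponse],
    params: ParameterSet | None = None,
) -> dict[str, ConditionCurve]:
    """Per-condition, per-bin across-trial response curves."""
    params = params or ParameterSet()
    edges = _bin_edges(params)
    starts = edges[:-1]
    curves: dict[str, ConditionCurve] = {}
    for cond in ("AU", "UA", "UU"):
        rs = [r for r in responses if r.condition == cond]
        samples: list[np.ndarray] = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            samples.append(np.array([r.response for r in rs if lo <= r.onset_rel < hi]))
        curves[cond] = ConditionCurve(cond, starts.copy(), samples)
    return curves


def normalize_curves(
    au: ConditionCurve,
    ua: ConditionCurve,
    uu: ConditionCurve,
) -> tuple[ConditionCurve, ConditionCurve]:
    """Subtract the UU control's per-bin mean from the AU and UA samples.

    The per-trial samples are retained (shifted by the UU bin mean) so the
    per-bin significance test can be run on the normalized activity.
    """
    out = []
    uu_mean = uu.mean
    centered_uu = [
        s - uu_mean[i] if s.size else np.array([]) for i, s in enumerate(uu.samples)
    ]
    for curve in (au, ua):
        if curve.bin_starts.shape != uu.bin_starts.shape or np.any(curve.bin_starts != uu.bin_starts):
            raise ValueError("condition curves have mismatching bins")
        shifted = [
            s - uu_mean[i] if (s.size and np.isfinite(uu_mean[i])) else np.array([])
            for i, s in enumerate(curve.samples)
        ]
        out.append(
            ConditionCurve(curve.condition + "-UU", curve.bin_starts.copy(), shifted, ref_samples=centered_uu)
        )
    return out[0], out[1]


def _bin_p_values(curve: ConditionCurve) -> np.ndarray:
    """One-sided p-value per bin for mean > 0; 1.0 where untestable.

    When the curve carries the (zero-centered) control samples, a Welch
    two-sample test is used so the control's own sampling uncertainty
    enters the test; otherwise a one-sample t-test.
    """
    ps = np.ones(len(curve.samples))
    for i, s in enumerate(curve.samples):
        if s.size < 2 or s.std(ddof=1) == 0:
            continue
        ref = curve.ref_samples[i] if curve.ref_samples is not None else None
        if ref is not None and ref.size >= 2 and ref.std(ddof=1) > 0:
            ps[i] = stats.ttest_ind(s, ref, equal_var=False, alternative="greater").pvalue
        else:
            ps[i] = stats.ttest_1samp(s, 0.0, alternative="greater").pvalue
    return ps


def detect_change(normalized: ConditionCurve, kind: str, alpha: float = ALPHA) -> ChangePointResult:
    """Three-consecutive-window change-point rule, scanning from trial start.

    ``offset-in-AU``: the first bin opening a run of three consecutive
    windows whose normalized activity is *not* significantly greater than
    zero.  ``onset-in-UA``: the first bin opening a run of three
    consecutive significantly-positive windows.  ``None`` when no
    qualifying run exists.
    """
    if kind not in ("offset-in-AU", "onset-in-UA"):
        raise ValueError(f"unknown change-point kind {kind!r}")
    ps = _bin_p_values(normalized)
    qualifying = (ps >= alpha) if kind == "offset-in-AU" else (ps < alpha)
    time_ms: float | None = None
    for i in range(len(qualifying) - RUN_LENGTH + 1):
        if qualifying[i : i + RUN_LENGTH].all():
            time_ms = float(normalized.bin_starts[i])
            break
    return ChangePointResult(kind=kind, time_ms=time_ms, p_values=ps, bin_starts=normalized.bin_starts.copy())


def visual_noise_floor(responses: np.ndarray, uu_curve: ConditionCurve) -> np.ndarray:
    """Visualization threshold: subtract half the maximum UU response,
    bounding at zero."""
    thr = float(np.nanmax(uu_curve.mean)) / 2.0
    return np.maximum(0.0, np.asarray(responses, dtype=float) - thr)


def analyze_records(
    records: list[TrialRecord],
    params: ParameterSet | None = None,
    geometry: FieldGeometry | None = None,
) -> AnalysisSummary:
    """Full pipeline: reverse correlation -> curves -> normalization ->
    change points."""
    params = params or ParameterSet()
    responses = reverse_correlate(records, params, geometry)
    curves = build_condition_curves(responses, params)
    au_norm, ua_norm = normalize_curves(curves["AU"], curves["UA"], curves["UU"])
    return AnalysisSummary(
        au=curves["AU"],
        ua=curves["UA"],
        uu=curves["UU"],
        au_norm=au_norm,
        ua_norm=ua_norm,
        offset_au=detect_change(au_norm, "offset-in-AU"),
        onset_ua=detect_change(ua_norm, "onset-in-UA"),
    )
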
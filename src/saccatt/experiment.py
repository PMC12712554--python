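"""Replication protocol: trials, batches, lesions and robustness variants.

A trial presents 700 ms of random probe bars around a guided 5° rightward
saccade (onset at 350 ms) while an endogenous attention pointer is held at
one of four positions (above/below the fixation point or the saccade
target).  Trials sharing a schedule are simulated as blocks with a common
saccade/attention context and per-trial random bar streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .dynamics import EyeAxis
from .geometry import FieldGeometry, gaussian_blob
from .network import LesionConfig, Model, ModelState, StepSignals, build_model, lip_projection_to_v4, step_model
from .params import ParameterSet
from .signals import (
    AttentionSchedule,
    BarStimulus,
    EyeTrajectory,
    attention_amplitude,
    cd_seed_signal,
    generate_bar_stream,
    make_eye_trajectory,
    pc_amplitudes,
)

__all__ = [
    "FP",
    "ST",
    "AP_POSITIONS",
    "TrialConfig",
    "TrialRecord",
    "ap_position",
    "run_trial",
    "run_block",
    "run_batch",
    "classify_condition",
    "perturb_parameters",
    "run_robustness",
]

#: head-centered fixation point and saccade target of the task
FP: tuple[float, float] = (0.0, 0.0)
ST: tuple[float, float] = (5.0, 0.0)

#: the four cued attention positions, indexed 0..3
AP_POSITIONS: tuple[str, ...] = ("above-fp", "below-fp", "above-st", "below-st")


def ap_position(ap_index: int, params: ParameterSet | None = None) -> tuple[float, float]:
    """Head-centered attention position for an AP index (0..3)."""
    params = params or ParameterSet()
    off = params.ap_offset_deg
    base, sign = ((FP, 1), (FP, -1), (ST, 1), (ST, -1))[ap_index]
    return (base[0], base[1] + sign * off)


@dataclass(frozen=True)
class TrialConfig:
    """Full description of one trial."""

    ap_index: int = 0
    mode: Literal["tonic", "fading"] = "tonic"
    turnoff_time: float | None = None  # ms relative to saccade onset
    seed: int = 0
    lesions: LesionConfig = field(default_factory=LesionConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.ap_index <= 3:
            raise ValueError("ap_index must be in 0..3")
        if self.mode == "fading" and self.turnoff_time is None:
            raise ValueError("fading mode requires turnoff_time")

    def schedule(self, params: ParameterSet | None = None) -> AttentionSchedule:
        return AttentionSchedule(
            ap=ap_position(self.ap_index, params),
            mode=self.mode,
            turnoff_time=self.turnoff_time,
        )

    def schedule_key(self) -> tuple:
        """Trials with equal keys can share a simulation block."""
        return (self.ap_index, self.mode, self.turnoff_time, dataclasses.astuple(self.lesions))


@dataclass
class TrialRecord:
    """Per-trial log sufficient for the reverse-correlation analysis."""

    config: TrialConfig
    bars: list[BarStimulus]
    trajectory: EyeTrajectory
    #: V4 L4 rate history on the two probe rows: (T, 2, nx), float32
    v4_rows: np.ndarray | None
    #: vertical coordinate (deg) of the two stored rows
    row_y: tuple[float, float]
    #: optional full V4 L4 history (T, ny, nx)
    v4_full: np.ndarray | None = None
    #: optional LIP->V4 contribution history at the AP row: (T, 2, nx)
    #: with axis 1 = (from_CD, from_PC)
    lip_rows: np.ndarray | None = None


# ---------------------------------------------------------------------- #
# block simulation                                                        #
# ---------------------------------------------------------------------- #
def _add_bar_patch(
    buf: np.ndarray,
    geometry: FieldGeometry,
    cx: float,
    cy: float,
    sigma: float,
    amp: float,
) -> None:
    """Add a Gaussian blob onto one trial's image, local-patch evaluation."""
    ny, nx = buf.shape
    res = geometry.neurons_per_deg
    r = int(np.ceil(3.5 * sigma * res))
    icx = cx * res + (nx - 1) / 2
    icy = cy * res + (ny - 1) / 2
    x0, x1 = max(0, int(icx) - r), min(nx, int(icx) + r + 1)
    y0, y1 = max(0, int(icy) - r), min(ny, int(icy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    dx = (np.arange(x0, x1) - icx) / res
    dy = (np.arange(y0, y1) - icy) / res
    patch = amp * np.exp(-(dy[:, None] ** 2 + dx[None, :] ** 2) / (2.0 * sigma**2))
    buf[y0:y1, x0:x1] += patch


def run_block(
    configs: Sequence[TrialConfig],
    params: ParameterSet | None = None,
    geometry: FieldGeometry | None = None,
    *,
    keep_full_history: bool = False,
    record_lip: bool = False,
) -> list[TrialRecord]:
    """Simulate a block of trials sharing one schedule.

    All trials must agree on (AP, attention mode/turnoff, lesions); they
    differ only in their bar-stream seeds.  The saccade/attention context
    (FEF cascade, Xh, attention pointer) is simulated once and shared.
    """
    params = params or ParameterSet()
    geometry = geometry or FieldGeometry()
    if not configs:
        return []
    key = configs[0].schedule_key()
    if any(c.schedule_key() != key for c in configs):
        raise ValueError("all trials of a block must share one schedule")

    model = build_model(params, configs[0].lesions, geometry)
    B = len(configs)
    dt = params.dt
    n_steps = int(round(params.trial_duration / dt))
    times = np.arange(n_steps) * dt

    trajectory = make_eye_trajectory(FP, ST, params.saccade_onset, geometry, params)
    schedule = configs[0].schedule(params)

    # precomputed scalar time courses
    att_amp = attention_amplitude(schedule, times, params.saccade_onset, params)
    st_ret = (ST[0] - FP[0], ST[1] - FP[1])
    cd_amp = cd_seed_signal(st_ret, params.saccade_onset, times, params)
    pc_old, pc_new = pc_amplitudes(trajectory, times, params)
    eye_xy = trajectory.position(times)  # (T, 2)

    att_blob = gaussian_blob(geometry, *schedule.ap, params.att_sigma)[None].astype(np.float32)
    cd_blob = gaussian_blob(geometry, *st_ret, params.cd_sigma)[None].astype(np.float32)
    eye_axis = model.eye_axis
    tune_fp = eye_axis.tuning(trajectory.fp[0])
    tune_st = eye_axis.tuning(trajectory.st[0])

    # per-trial bar streams and per-step active-bar buckets
    bars_per_trial = [generate_bar_stream(geometry, trajectory, c.seed, params) for c in configs]
    active: list[list[tuple[int, int]]] = [[] for _ in range(n_steps)]
    for i, bars in enumerate(bars_per_trial):
        for j, b in enumerate(bars):
            s0 = max(0, int(np.ceil(b.onset / dt)))
            s1 = min(n_steps, int(np.ceil(b.offset / dt)))
            for s in range(s0, s1):
                active[s].append((i, j))

    row_y = (params.ap_offset_deg, -params.ap_offset_deg)
    rows_idx = [geometry.to_index(0.0, y)[0] for y in row_y]

    state = model.initial_state(batch=B)
    rows_hist = np.zeros((n_steps, B, 2, geometry.nx), dtype=np.float32)
    full_hist = np.zeros((n_steps, B) + geometry.shape, dtype=np.float32) if keep_full_history else None
    lip_hist = np.zeros((n_steps, B, 2, geometry.nx), dtype=np.float32) if record_lip else None

    vis = np.zeros((B,) + geometry.shape, dtype=np.float32)
    ap_row = rows_idx[0] if schedule.ap[1] >= 0 else rows_idx[1]

    for s in range(n_steps):
        t = times[s]
        vis[:] = 0.0
        ex, ey = eye_xy[s]
        for i, j in active[s]:
            b = bars_per_trial[i][j]
            _add_bar_patch(vis[i], geometry, b.x_deg - ex, b.y_deg - ey, params.bar_sigma, params.bar_amplitude)
        np.clip(vis, 0.0, params.saturation, out=vis)

        signals = StepSignals(
            vis=vis,
            att=att_amp[s] * att_blob,
            cd_drive=cd_amp[s] * cd_blob,
            pc_eye=pc_old[s] * tune_fp + pc_new[s] * tune_st,
        )
        state = step_model(model, state, signals, dt)

        rows_hist[s] = state.v4l4[:, rows_idx, :]
        if full_hist is not None:
            full_hist[s] = state.v4l4
        if lip_hist is not None:
            from_cd, from_pc, _ = lip_projection_to_v4(model, state)
            lip_hist[s, :, 0, :] = from_cd[:, ap_row, :]
            lip_hist[s, :, 1, :] = from_pc[:, ap_row, :]

    records = []
    for i, c in enumerate(configs):
        records.append(
            TrialRecord(
                config=c,
                bars=bars_per_trial[i],
                trajectory=trajectory,
                v4_rows=rows_hist[:, i],
                row_y=row_y,
                v4_full=full_hist[:, i] if full_hist is not None else None,
                lip_rows=lip_hist[:, i] if lip_hist is not None else None,
            )
        )
    return records


def run_trial(
    config: TrialConfig,
    params: ParameterSet | None = None,
    geometry: FieldGeometry | None = None,
    **kwargs,
) -> TrialRecord:
    """Simulate a single trial (deterministic given its seed)."""
    return run_block([config], params, geometry, **kwargs)[0]


def _trial_seed(master_seed: int, index: int) -> int:
    return (master_seed * 100_003 + 7919 * index + 1) % (2**31)


def run_batch(
    n_trials: int,
    ap_policy: str = "above-fp",
    seed: int = 0,
    params: ParameterSet | None = None,
    *,
    mode: Literal["tonic", "fading"] = "tonic",
    turnoff_time: float | None = None,
    lesions: LesionConfig | None = None,
    block_size: int = 32,
    geometry: FieldGeometry | None = None,
) -> list[TrialRecord]:
    """Simulate a batch of trials with reproducibly derived per-trial seeds.

    ``ap_policy`` is either ``"uniform"`` (cycle through the four APs) or
    one of the fixed positions (``"above-fp"``, ``"below-fp"``,
    ``"above-st"``, ``"below-st"``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or ParameterSet()
    lesions = lesions or LesionConfig()
    if ap_policy == "uniform":
        ap_indices = [i % 4 for i in range(n_trials)]
    elif ap_policy in AP_POSITIONS:
        ap_indices = [AP_POSITIONS.index(ap_policy)] * n_trials
    else:
        raise ValueError(f"unknown ap_policy {ap_policy!r}")

    configs = [
        TrialConfig(
            ap_index=ap_indices[i],
            mode=mode,
            turnoff_time=turnoff_time,
            seed=_trial_seed(seed, i),
            lesions=lesions,
        )
        for i in range(n_trials)
    ]

    records: list[TrialRecord] = []
    by_key: dict[tuple, list[TrialConfig]] = {}
    for c in configs:
        by_key.setdefault(c.schedule_key(), []).append(c)
    for group in by_key.values():
        for i in range(0, len(group), block_size):
            records.extend(run_block(group[i : i + block_size], params, geometry))
    return records


# ---------------------------------------------------------------------- #
# condition classification                                                #
# ---------------------------------------------------------------------- #
def classify_condition(
    neuron_rf_pre: tuple[float, float],
    saccade_vector: tuple[float, float],
    ap: tuple[float, float],
    ap_control: tuple[float, float],
    tolerance_deg: float,
) -> str:
    """Assign the AU/UA/UU condition of one neuron in one trial.

    ``neuron_rf_pre`` is the neuron's pre-saccadic receptive-field center
    (head-centered, eyes at FP).  After the saccade the same neuron covers
    ``rf_pre + saccade_vector``.  AU: attended before the saccade only;
    UA: attended after only; UU: the neuron's RF covers the vertically
    opposite control position (before or after), so it is unattended
    throughout and statistically matched to the AU/UA populations.
    """
    if tolerance_deg <= 0:
        raise ValueError("tolerance must be > 0")

    def near(p: tuple[float, float], q: tuple[float, float]) -> bool:
        return float(np.hypot(p[0] - q[0], p[1] - q[1])) <= tolerance_deg

    rf_post = (neuron_rf_pre[0] + saccade_vector[0], neuron_rf_pre[1] + saccade_vector[1])
    pre_att = near(neuron_rf_pre, ap)
    post_att = near(rf_post, ap)
    if pre_att and not post_att:
        return "AU"
    if post_att and not pre_att:
        return "UA"
    if pre_att and post_att:
        return "none"
    if near(neuron_rf_pre, ap_control) or near(rf_post, ap_control):
        return "UU"
    return "none"


# ---------------------------------------------------------------------- #
# robustness harness                                                      #
# ---------------------------------------------------------------------- #
def perturb_parameters(
    base: ParameterSet,
    magnitude: float,
    seed: int,
) -> ParameterSet:
    """Multiply every robustness-eligible parameter by U(1-m, 1+m)."""
    names = base.robustness_names()
    if not names:
        raise ValueError("no robustness-eligible parameters flagged")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - magnitude, 1.0 + magnitude, size=len(names))
    changes = {name: getattr(base, name) * f for name, f in zip(names, factors)}
    return base.replace(**changes)


def run_robustness(
    n_parameter_sets: int,
    trials_per_set: int,
    seed: int,
    base_params: ParameterSet | None = None,
    magnitude: float = 0.05,
    **batch_kwargs,
):
    """Re-run the experiment under randomly perturbed parameter sets.

    All sets share the same stimulus stream (same batch seed) so that
    differences between sets isolate the parameter perturbation; returns
    per-set analysis summaries plus the across-set mean and standard
    deviation of the normalized AU/UA curves.
    """
    from . import analysis

    base_params = base_params or ParameterSet()
    summaries = []
    for k in range(n_parameter_sets):
        pset = perturb_parameters(base_params, magnitude, seed=_trial_seed(seed, k)) if magnitude > 0 else base_params
        records = run_batch(trials_per_set, "above-fp", seed=seed, params=pset, **batch_kwargs)
        summaries.append(analysis.analyze_records(records, params=pset))
    au = np.stack([s.au_norm.mean for s in summaries])
    ua = np.stack([s.ua_norm.mean for s in summaries])
    aggregate = {
        "au_mean": np.nanmean(au, axis=0),
        "au_std": np.nanstd(au, axis=0),
        "ua_mean": np.nanmean(ua, axis=0),
        "ua_std": np.nanstd(ua, axis=0),
        "bin_starts": summaries[0].au_norm.bin_starts,
    }
    return summaries, aggregate
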
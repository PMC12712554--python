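"""The five generated model inputs.

The experiment presents no external data; every input is generated:

* a visual stream of briefly flashed bars (retinotopic, via the eye
  trajectory),
* the eye trajectory of the guided saccade (fixation point FP to saccade
  target ST),
* a proprioceptive (PC) eye-position signal in head-centered coordinates
  that updates only after the saccade has ended,
* a corollary-discharge (CD) seed driving FEF visual cells at the
  retinotopic saccade target, and
* an endogenous attention pointer at the cued attention position (AP) in
  head-centered coordinates, either tonic or fading.

All generators are pure functions of (parameters, seed); frames never
change within a trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .geometry import FieldGeometry, gaussian_blob
from .params import ParameterSet

__all__ = [
    "EyeTrajectory",
    "BarStimulus",
    "AttentionSchedule",
    "SignalTimecourse",
    "saccade_duration",
    "make_eye_trajectory",
    "generate_bar_stream",
    "render_visual_input",
    "pc_amplitudes",
    "pc_signal",
    "cd_seed_signal",
    "attention_amplitude",
    "attention_signal",
]


# ---------------------------------------------------------------------- #
# eye trajectory                                                          #
# ---------------------------------------------------------------------- #
def saccade_duration(amplitude_deg: float, params: ParameterSet | None = None) -> float:
    """Saccade duration (ms) from the amplitude-duration main sequence.

    An affine main-sequence relation ``D = intercept + slope * A`` with
    defaults producing the 67 ms, 5° horizontal saccade of the simulated
    experiment.  A zero-amplitude "saccade" has zero duration.
    """
    params = params or ParameterSet()
    if amplitude_deg < 0:
        raise ValueError("saccade amplitude must be >= 0")
    if amplitude_deg == 0:
        return 0.0
    return params.saccade_duration_intercept + params.saccade_duration_slope * amplitude_deg


@dataclass(frozen=True)
class EyeTrajectory:
    """Eye position (degrees, head-centered) over the trial.

    The movement follows a smooth raised-cosine position profile between
    fixation point and saccade target; position is exactly ``fp`` before
    ``saccade_onset`` and exactly ``st`` from ``saccade_end`` onward.
    """

    fp: tuple[float, float]
    st: tuple[float, float]
    saccade_onset: float
    saccade_duration: float

    @property
    def saccade_end(self) -> float:
        return self.saccade_onset + self.saccade_duration

    @property
    def amplitude(self) -> float:
        return math.hypot(self.st[0] - self.fp[0], self.st[1] - self.fp[1])

    @property
    def vector(self) -> tuple[float, float]:
        return (self.st[0] - self.fp[0], self.st[1] - self.fp[1])

    def position(self, t):
        """Eye position at time ``t`` (ms); broadcasts over arrays."""
        t = np.asarray(t, dtype=float)
        if self.saccade_duration == 0:
            frac = np.where(t >= self.saccade_onset, 1.0, 0.0)
        else:
            u = np.clip((t - self.saccade_onset) / self.saccade_duration, 0.0, 1.0)
            frac = 0.5 * (1.0 - np.cos(np.pi * u))
        x = self.fp[0] + frac * (self.st[0] - self.fp[0])
        y = self.fp[1] + frac * (self.st[1] - self.fp[1])
        if x.ndim == 0:
            return (float(x), float(y))
        return np.stack([x, y], axis=-1)


def make_eye_trajectory(
    fp: tuple[float, float],
    st: tuple[float, float],
    onset: float,
    geometry: FieldGeometry | None = None,
    params: ParameterSet | None = None,
) -> EyeTrajectory:
    """Build the trial's eye trajectory from FP to ST starting at ``onset``."""
    geometry = geometry or FieldGeometry()
    geometry.check_inside(*fp, what="fixation point")
    geometry.check_inside(*st, what="saccade target")
    amplitude = math.hypot(st[0] - fp[0], st[1] - fp[1])
    duration = saccade_duration(amplitude, params)
    return EyeTrajectory(fp=tuple(fp), st=tuple(st), saccade_onset=float(onset), saccade_duration=duration)


# ---------------------------------------------------------------------- #
# bar stimulus stream                                                     #
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class BarStimulus:
    """One flashed probe bar, head-centered."""

    x_deg: float
    y_deg: float
    onset: float
    duration: float
    side: Literal["above", "below"]

    @property
    def offset(self) -> float:
        return self.onset + self.duration


def generate_bar_stream(
    geometry: FieldGeometry,
    trajectory: EyeTrajectory,
    seed: int,
    params: ParameterSet | None = None,
) -> list[BarStimulus]:
    """Random probe-bar stream for one trial.

    Bars are flashed above and below the horizontal center line (at the
    probe-row eccentricity) with horizontal positions uniform over the
    field width on the integer-degree grid, onsets within ±300 ms of
    saccade onset, durations 5-20 ms.  Anti-clustering constraints: per
    side a minimum onset spacing, and a minimum 2° center distance between
    concurrently visible bars of the same side.
    """
    params = params or ParameterSet()
    rng = np.random.default_rng(seed)
    t_lo = trajectory.saccade_onset - params.bar_window
    t_hi = trajectory.saccade_onset + params.bar_window
    half_w = geometry.width_deg / 2.0
    xs_grid = np.arange(-math.floor(half_w), math.floor(half_w) + 1, dtype=float)

    bars: list[BarStimulus] = []
    for side, y in (("above", params.ap_offset_deg), ("below", -params.ap_offset_deg)):
        t = t_lo + rng.uniform(0.0, params.bar_mean_gap)
        placed: list[BarStimulus] = []
        while t < t_hi:
            duration = rng.uniform(params.bar_duration_min, params.bar_duration_max)
            # reject x too close to a concurrently visible bar on this side
            for _ in range(20):
                x = float(rng.choice(xs_grid))
                clash = any(
                    abs(x - b.x_deg) < params.bar_min_distance
                    and t < b.offset
                    and b.onset < t + duration
                    for b in placed[-6:]
                )
                if not clash:
                    break
            placed.append(BarStimulus(x_deg=x, y_deg=y, onset=float(t), duration=float(duration), side=side))
            t += params.bar_min_onset_gap + rng.exponential(
                max(params.bar_mean_gap - params.bar_min_onset_gap, 1e-9)
            )
        bars.extend(placed)
    bars.sort(key=lambda b: (b.onset, b.side, b.x_deg))
    return bars


def render_visual_input(
    bars: list[BarStimulus],
    trajectory: EyeTrajectory,
    t: float,
    geometry: FieldGeometry | None = None,
    params: ParameterSet | None = None,
) -> np.ndarray:
    """Retinotopic visual image at time ``t``.

    Each bar currently visible appears as a Gaussian blob at its
    head-centered position minus the current eye position; blobs beyond
    the field border are clipped by it.
    """
    geometry = geometry or FieldGeometry()
    params = params or ParameterSet()
    ex, ey = trajectory.position(t)
    img = np.zeros(geometry.shape)
    for b in bars:
        if b.onset <= t < b.offset:
            img += gaussian_blob(geometry, b.x_deg - ex, b.y_deg - ey, params.bar_sigma, params.bar_amplitude)
    return np.clip(img, 0.0, params.saturation)


# ---------------------------------------------------------------------- #
# proprioceptive eye-position signal                                      #
# ---------------------------------------------------------------------- #
def pc_amplitudes(trajectory: EyeTrajectory, t, params: ParameterSet | None = None):
    """Amplitudes (old-position, new-position) of the PC signal at ``t``.

    The PC signal holds the pre-saccadic eye position until
    ``saccade_end + pc_update_delay`` and then swaps amplitude to the
    post-saccadic position over ``pc_swap_duration`` ("jump-like": no
    intermediate positions are ever activated; the two amplitudes
    cross-fade, sum to one, and the swap completes in finite time).
    """
    params = params or ParameterSet()
    t = np.asarray(t, dtype=float)
    if trajectory.saccade_duration == 0:
        new = np.zeros_like(t)
    else:
        t_up = trajectory.saccade_end + params.pc_update_delay
        u = np.clip((t - t_up) / params.pc_swap_duration, 0.0, 1.0)
        new = 0.5 * (1.0 - np.cos(np.pi * u))
    return 1.0 - new, new


def pc_signal(
    trajectory: EyeTrajectory,
    t: float,
    geometry: FieldGeometry | None = None,
    params: ParameterSet | None = None,
) -> np.ndarray:
    """Head-centered PC eye-position map at time ``t``."""
    geometry = geometry or FieldGeometry()
    params = params or ParameterSet()
    a_old, a_new = pc_amplitudes(trajectory, t, params)
    out = gaussian_blob(geometry, *trajectory.fp, params.pc_sigma, float(a_old))
    if float(a_new) > 0:
        out = out + gaussian_blob(geometry, *trajectory.st, params.pc_sigma, float(a_new))
    return out


# ---------------------------------------------------------------------- #
# corollary-discharge seed                                                #
# ---------------------------------------------------------------------- #
def cd_seed_signal(
    st_retinotopic: tuple[float, float],
    saccade_onset: float,
    t,
    params: ParameterSet | None = None,
):
    """Scalar amplitude of the CD drive to FEF visual cells at time ``t``.

    A sigmoidal build-up of activity at the retinotopic ST before the
    saccade (saccade planning) followed by an exponential decay after
    saccade onset; near zero long before and long after the movement, with
    a single peak at saccade onset.
    """
    params = params or ParameterSet()
    t = np.asarray(t, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(t - (saccade_onset - params.cd_rise_center)) / params.cd_rise_width))
    decay = np.exp(-np.maximum(t - saccade_onset, 0.0) / params.cd_decay_tau)
    out = rise * decay
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------- #
# endogenous attention pointer                                            #
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class AttentionSchedule:
    """Endogenous attention pointer schedule.

    ``mode='tonic'`` keeps the pointer input active for the whole trial;
    ``mode='fading'`` switches it off at ``turnoff_time`` (ms relative to
    saccade onset) after which the amplitude decays exponentially.
    """

    ap: tuple[float, float]
    mode: Literal["tonic", "fading"] = "tonic"
    turnoff_time: float | None = None
    decay_constant: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("tonic", "fading"):
            raise ValueError(f"unknown attention mode {self.mode!r}")
        if self.mode == "fading" and self.turnoff_time is None:
            raise ValueError("fading schedule requires turnoff_time")


def attention_amplitude(
    schedule: AttentionSchedule,
    t,
    saccade_onset: float,
    params: ParameterSet | None = None,
):
    """Amplitude of the attention input at time ``t`` (ms from trial start).

    The pointer builds up with a fast onset component plus a slow
    consolidation component; in fading mode it decays exponentially after
    the turnoff time.
    """
    params = params or ParameterSet()
    t = np.asarray(t, dtype=float)
    amp = params.att_amp_fast * (1.0 - np.exp(-np.maximum(t, 0.0) / params.att_tau_fast)) + (
        params.att_amp_slow * (1.0 - np.exp(-np.maximum(t, 0.0) / params.att_tau_slow))
    )
    if schedule.mode == "fading":
        tau = schedule.decay_constant or params.att_fade_tau
        t_off = saccade_onset + float(schedule.turnoff_time)
        amp = amp * np.where(t > t_off, np.exp(-(t - t_off) / tau), 1.0)
    out = amp
    return float(out) if out.ndim == 0 else out


def attention_signal(
    schedule: AttentionSchedule,
    t: float,
    saccade_onset: float = 350.0,
    geometry: FieldGeometry | None = None,
    params: ParameterSet | None = None,
) -> np.ndarray:
    """Head-centered attention-pointer map at time ``t``."""
    geometry = geometry or FieldGeometry()
    params = params or ParameterSet()
    amp = attention_amplitude(schedule, t, saccade_onset, params)
    return gaussian_blob(geometry, *schedule.ap, params.att_sigma, float(amp))


# ---------------------------------------------------------------------- #
# generic signal wrapper                                                  #
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SignalTimecourse:
    """A named drive signal: its kind, fixed reference frame and value(t)."""

    kind: Literal["visual", "attention", "PC", "CD"]
    frame: Literal["retinotopic", "head-centered"]
    value: Callable[[float], np.ndarray]

    def __call__(self, t: float) -> np.ndarray:
        return self.value(t)
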
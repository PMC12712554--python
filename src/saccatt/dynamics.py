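"""Core numerics: leaky rate maps, gain modulation and RBF frame transforms.

Every population in the model is a map of nonnegative firing rates on a
spatial grid, integrated with explicit Euler steps of the leaky rate
equation

    tau * dr/dt = -r + F( drive * prod_i (1 + g_i * mod_i) )

where ``F`` is rectifying-saturating (piecewise linear, saturation 1) and
the modulatory inputs enter multiplicatively (gain fields): modulation
without feedforward drive produces no response.

Reference-frame transformation uses radial-basis-function (RBF) maps: a
combined population tuned jointly to a retinotopic position ``x`` and an
eye-related value ``e``.  A head-centered readout sums all combined nodes
with ``x + e = h``; a retinotopic readout marginalises the eye axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import FieldGeometry
from .params import ParameterSet

__all__ = [
    "RateMap",
    "EyeAxis",
    "Projection",
    "rectify_saturate",
    "euler_step",
    "step_map",
    "gain_modulate",
    "rbf_combine",
    "embed_headcentered",
    "rbf_readout_headcentered",
    "rbf_readout_retinotopic",
    "smooth_projection",
    "lateral_spread",
]

Frame = Literal["retinotopic", "head-centered", "combined"]


def rectify_saturate(x: np.ndarray, saturation: float = 1.0) -> np.ndarray:
    """Piecewise-linear transfer: rectified below 0, saturated above."""
    return np.clip(x, 0.0, saturation)


def gain_modulate(feedforward: np.ndarray, modulation: np.ndarray, gain: float) -> np.ndarray:
    """Multiplicative gain field: ``feedforward * (1 + gain * modulation)``.

    Zero modulation is the identity; zero feedforward yields zero output
    regardless of modulation (modulation alone drives nothing).
    """
    feedforward = np.asarray(feedforward, dtype=float)
    modulation = np.asarray(modulation, dtype=float)
    if feedforward.shape != modulation.shape:
        raise ValueError(
            f"shape mismatch: feedforward {feedforward.shape} vs modulation {modulation.shape}"
        )
    return feedforward * (1.0 + gain * modulation)


def euler_step(
    rates: np.ndarray,
    drive: np.ndarray,
    modulatory: Sequence[tuple[float, np.ndarray]] = (),
    *,
    tau: float,
    dt: float = 1.0,
    saturation: float = 1.0,
) -> np.ndarray:
    """One explicit-Euler step of the leaky gain-modulated rate equation."""
    if not np.isfinite(tau) or tau <= 0:
        raise ValueError(f"time constant must be positive and finite, got {tau!r}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    total = np.asarray(drive, dtype=float)
    for gain, mod in modulatory:
        total = gain_modulate(total, mod, gain)
    target = rectify_saturate(total, saturation)
    out = rates + (dt / tau) * (target - rates)
    return np.clip(out, 0.0, saturation)


@dataclass
class RateMap:
    """A population of nonnegative rates on a grid in a declared frame."""

    rates: np.ndarray
    frame: Frame = "retinotopic"
    geometry: FieldGeometry | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if (self.rates < 0).any():
            raise ValueError("rates must be nonnegative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.rates.shape

    def copy(self) -> "RateMap":
        return RateMap(self.rates.copy(), self.frame, self.geometry)


def step_map(
    rate_map: RateMap,
    driving_input: np.ndarray,
    modulatory_inputs: Sequence[tuple[float, np.ndarray]] = (),
    params: ParameterSet | None = None,
    dt: float | None = None,
    *,
    tau: float | None = None,
) -> RateMap:
    """Advance a :class:`RateMap` by one Euler step (returns a new map)."""
    params = params or ParameterSet()
    tau = params.tau_v1 if tau is None else tau
    dt = params.dt if dt is None else dt
    new = euler_step(
        rate_map.rates,
        driving_input,
        modulatory_inputs,
        tau=tau,
        dt=dt,
        saturation=params.saturation,
    )
    return RateMap(new, rate_map.frame, rate_map.geometry)


# ---------------------------------------------------------------------- #
# RBF reference-frame machinery                                           #
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class EyeAxis:
    """Discretised eye-position axis of the combined RBF maps.

    The saccade of the task is purely horizontal, so the eye axis covers
    only the horizontal eye position, on a coarse integer-degree grid.
    """

    values: tuple[float, ...] = (-10.0, -5.0, 0.0, 5.0, 10.0, 15.0)
    sigma: float = 1.5

    @property
    def n(self) -> int:
        return len(self.values)

    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def tuning(self, e0: float) -> np.ndarray:
        """Gaussian tuning of each eye-axis node to eye position ``e0``."""
        e = self.array()
        return np.exp(-((e - e0) ** 2) / (2.0 * self.sigma**2))

    def norm(self) -> float:
        """Summed tuning at an on-grid eye position (readout scale factor)."""
        return float(self.tuning(self.values[len(self.values) // 2]).sum())


def rbf_combine(
    retinotopic: np.ndarray,
    eye_profile: np.ndarray,
) -> np.ndarray:
    """Combined-frame RBF response: outer product of the two tunings.

    ``retinotopic`` has shape ``(..., ny, nx)``; ``eye_profile`` has shape
    ``(ne,)``.  The combined map ``(..., ny, nx, ne)`` responds maximally
    where both inputs peak and is all-zero if either input is.
    """
    retinotopic = np.asarray(retinotopic, dtype=float)
    eye_profile = np.asarray(eye_profile, dtype=float)
    return retinotopic[..., None] * eye_profile


def embed_headcentered(
    head_map: np.ndarray,
    eye_axis: EyeAxis,
    geometry: FieldGeometry,
) -> np.ndarray:
    """Project a head-centered map onto combined-frame coordinates.

    Node ``(y, x, e)`` receives the head-centered activity at
    ``(y, x + e)``: each eye-position slice is the head map shifted
    against that slice's eye position.  Positions outside the head grid
    contribute zero.
    """
    head_map = np.asarray(head_map, dtype=float)
    nx = head_map.shape[-1]
    out = np.zeros(head_map.shape + (eye_axis.n,))
    for j, e in enumerate(eye_axis.values):
        shift = int(round(e * geometry.neurons_per_deg))
        if shift == 0:
            out[..., j] = head_map
        elif shift > 0:
            out[..., : nx - shift, j] = head_map[..., shift:]
        else:
            out[..., -shift:, j] = head_map[..., :shift]
    return out


def rbf_readout_headcentered(
    combined: np.ndarray,
    eye_axis: EyeAxis,
    geometry: FieldGeometry,
) -> np.ndarray:
    """Head-centered readout: ``h`` sums all nodes with ``x + e = h``."""
    combined = np.asarray(combined, dtype=float)
    nx = combined.shape[-2]
    out = np.zeros(combined.shape[:-1])
    for j, e in enumerate(eye_axis.values):
        shift = int(round(e * geometry.neurons_per_deg))
        sl = combined[..., j]
        if shift == 0:
            out += sl
        elif shift > 0:
            out[..., shift:] += sl[..., : nx - shift]
        else:
            out[..., :shift] += sl[..., -shift:]
    return out


def rbf_readout_retinotopic(combined: np.ndarray) -> np.ndarray:
    """Retinotopic readout: marginalise (sum) the eye-position axis."""
    return np.asarray(combined, dtype=float).sum(axis=-1)


def lateral_spread(activity: np.ndarray, sigma_deg: float, geometry: FieldGeometry) -> np.ndarray:
    """Saturating lateral excitatory spread along the horizontal axis.

    Each node receives the envelope (maximum) of its neighbours' activity
    weighted by a Gaussian of ``sigma_deg``; the center value is
    preserved, so the spread widens a narrow activity profile without
    attenuating it (saturating lateral synapses).
    """
    activity = np.asarray(activity, dtype=float)
    if sigma_deg <= 0:
        return activity
    out = activity.copy()
    reach = int(np.ceil(2.5 * sigma_deg * geometry.neurons_per_deg))
    for k in range(1, reach + 1):
        w = float(np.exp(-(k / geometry.neurons_per_deg) ** 2 / (2.0 * sigma_deg**2)))
        np.maximum(out[..., :-k], w * activity[..., k:], out=out[..., :-k])
        np.maximum(out[..., k:], w * activity[..., :-k], out=out[..., k:])
    return out


def smooth_projection(rates: np.ndarray, sigma_deg: float, geometry: FieldGeometry) -> np.ndarray:
    """Distance-dependent (Gaussian) projection kernel between aligned maps.

    Normalised so a uniform input maps to itself; applied over the two
    trailing spatial axes, supporting a leading batch axis.
    """
    if sigma_deg <= 0:
        return np.asarray(rates, dtype=float)
    sigma_px = sigma_deg * geometry.neurons_per_deg
    rates = np.asarray(rates, dtype=float)
    sig = (0.0,) * (rates.ndim - 2) + (sigma_px, sigma_px)
    return gaussian_filter(rates, sigma=sig, mode="constant")


@dataclass
class Projection:
    """A named, lesionable pathway between two maps."""

    source: str
    target: str
    mode: Literal["driving", "modulatory"]
    gain: float = 1.0
    kernel_sigma: float = 0.0
    enabled: bool = True

    def describe(self) -> str:
        state = "on" if self.enabled else "OFF"
        return f"{self.source} -> {self.target} [{self.mode}, g={self.gain:g}, {state}]"
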
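"""Model parameters.

Every scalar constant of the model lives in :class:`ParameterSet`: time
constants and gains of the rate ODEs, connection strengths and kernel
widths, and the parameters of the five generated input signals.  The set
is serialisable to/from YAML so a run is fully described by its config.

Parameters fall into two groups mirroring how the robustness analysis
treats them: constants of the neuron ODEs and of the connections between
maps are *robustness-eligible* (they are the ones perturbed by ±5% in the
robustness harness), whereas the input-signal parameters define the
experimental stimulation itself and are held fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import yaml

__all__ = ["ParameterSet", "ROBUSTNESS_ELIGIBLE"]


#: names of the ODE / connection parameters varied in the robustness analysis
ROBUSTNESS_ELIGIBLE: tuple[str, ...] = (
    # time constants (ms)
    "tau_v1",
    "tau_v4l4",
    "tau_v4l23",
    "tau_fefv",
    "tau_fefvm",
    "tau_fefm",
    "tau_xh",
    "tau_lip",
    "tau_ptr",
    "tau_ptr_trace",
    # feedforward / driving connection strengths
    "w_v1_v4",
    "w_v4_pool",
    "w_fefv_fefvm",
    "w_fefvm_fefm",
    "w_att_lip",
    "w_v4_lip",
    "w_fefvm_lip",
    "w_fefm_xh",
    # modulatory gains
    "g_fef_v4",
    "g_lip_v4",
    # attention-pointer working-memory loops
    "w_ptr_self",
    "w_ptr_trace",
    "k_ptr_trace",
    "theta_ptr_trace",
    "theta_ptr_feedback",
    "sigma_ptr_spread",
    "ptr_trace_max",
    # thresholds
    "theta_fefm",
    # kernel widths (degrees)
    "sigma_pool",
    "sigma_lip_v4",
    "sigma_fef_v4",
    "sigma_eye_axis",
)


@dataclass
class ParameterSet:
    """Complete scalar parameterisation of the model.

    Units: time constants and times in ms, spatial widths in degrees,
    rates and amplitudes dimensionless in [0, saturation].
    """

    # ------------------------------------------------------------------ #
    # neuron ODEs (leaky rate units, explicit Euler)                      #
    # ------------------------------------------------------------------ #
    tau_v1: float = 5.0
    tau_v4l4: float = 6.0
    tau_v4l23: float = 10.0
    tau_fefv: float = 6.0
    tau_fefvm: float = 6.0
    tau_fefm: float = 6.0
    tau_xh: float = 5.0
    tau_lip: float = 5.0
    #: attention-pointer map (head-centered working-memory stage)
    tau_ptr: float = 4.0
    #: slow memory trace sustaining an established pointer
    tau_ptr_trace: float = 60.0
    #: rate saturation bound of every map
    saturation: float = 1.0

    # ------------------------------------------------------------------ #
    # connections                                                         #
    # ------------------------------------------------------------------ #
    w_v1_v4: float = 0.5
    w_v4_pool: float = 1.0
    w_fefv_fefvm: float = 1.0
    w_fefvm_fefm: float = 1.0
    #: FEF movement cells fire only above this visuomovement activity
    theta_fefm: float = 0.1
    #: attention pointer drive onto both LIP parts (has headroom > 1 so the
    #: LIP response saturates while the pointer is strong)
    w_att_lip: float = 1.0
    #: task-specific V4 drive into LIP
    w_v4_lip: float = 0.05
    #: FEFvm enhancement of ST-encoding LIP neurons
    w_fefvm_lip: float = 0.1
    #: FEFm drive into the head-centered transform map Xh
    w_fefm_xh: float = 1.0
    #: modulatory gain of FEFvm onto V4 L4
    g_fef_v4: float = 0.5
    #: modulatory gain of LIP (CD + PC parts) onto V4 L4
    g_lip_v4: float = 1.6
    #: spatial smoothing of the pooling projection V4 L4 -> L2/3
    sigma_pool: float = 1.0
    #: spatial smoothing of the LIP -> V4 gain projection
    sigma_lip_v4: float = 0.5
    #: spatial smoothing of the FEFvm -> V4 gain projection
    sigma_fef_v4: float = 0.8
    #: Gaussian tuning width along the eye-position axis of the RBF maps
    sigma_eye_axis: float = 1.2

    # Attention-pointer working-memory loops.  A fast self-excitation
    # ignites the pointer once its activity crosses the threshold; a slow
    # trace integrates supra-threshold activity and feeds back, so an
    # ignited pointer outlives its input for a duration that grows with
    # how long it has been established (and indefinitely once the trace
    # alone can hold the fast loop up).
    w_ptr_self: float = 1.9
    w_ptr_trace: float = 0.6
    k_ptr_trace: float = 3.9
    theta_ptr_trace: float = 0.68
    #: trace level below which the working-memory feedback disengages
    theta_ptr_feedback: float = 0.18
    #: lateral spread of the working-memory feedback within the pointer map
    sigma_ptr_spread: float = 1.0
    ptr_trace_max: float = 1.5

    # ------------------------------------------------------------------ #
    # input signals (experimental stimulation; not robustness-eligible)   #
    # ------------------------------------------------------------------ #
    #: visual bar blob: amplitude and width
    bar_amplitude: float = 1.0
    bar_sigma: float = 0.8
    #: endogenous attention: fast onset component + slow consolidation
    att_amp_fast: float = 0.5
    att_tau_fast: float = 25.0
    att_amp_slow: float = 0.3
    att_tau_slow: float = 200.0
    #: decay constant once a fading pointer is switched off
    att_fade_tau: float = 1.5
    att_sigma: float = 1.1
    #: vertical eccentricity of the attention position relative to FP/ST
    ap_offset_deg: float = 5.0
    #: proprioceptive eye-position signal
    pc_sigma: float = 1.5
    pc_update_delay: float = 60.0
    pc_swap_duration: float = 90.0
    #: corollary-discharge seed driving FEFv at the retinotopic ST
    cd_sigma: float = 1.5
    cd_rise_center: float = 104.0  # ms before saccade onset
    cd_rise_width: float = 8.0
    cd_decay_tau: float = 70.0

    # ------------------------------------------------------------------ #
    # kinematics and protocol timing                                      #
    # ------------------------------------------------------------------ #
    #: affine amplitude-duration main sequence D = intercept + slope * A
    saccade_duration_intercept: float = 42.0
    saccade_duration_slope: float = 5.0
    trial_duration: float = 700.0
    saccade_onset: float = 350.0
    bar_window: float = 300.0  # bars within ± this of saccade onset
    bar_min_onset_gap: float = 5.0  # per side, ms
    bar_min_distance: float = 4.0  # concurrently visible, same side, deg
    bar_mean_gap: float = 8.0  # mean onset spacing per side, ms
    bar_duration_min: float = 5.0
    bar_duration_max: float = 20.0
    #: RF-to-locus tolerance for AU/UA/UU condition assignment
    rf_tolerance_deg: float = 1.5
    dt: float = 1.0

    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self.names():
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} is not finite: {value!r}")
        for name in self.names():
            if name.startswith("tau_") and getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def robustness_names(cls) -> tuple[str, ...]:
        return ROBUSTNESS_ELIGIBLE

    def is_robustness_eligible(self, name: str) -> bool:
        return name in ROBUSTNESS_ELIGIBLE

    def copy(self) -> "ParameterSet":
        return dataclasses.replace(self)

    def replace(self, **kwargs: float) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def items(self) -> Iterator[tuple[str, float]]:
        for name in self.names():
            yield name, getattr(self, name)

    # -- serialisation -------------------------------------------------- #
    def to_dict(self) -> dict[str, float]:
        return {name: float(value) for name, value in self.items()}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ParameterSet":
        unknown = set(data) - set(cls.names())
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Short stable digest for logging/manifests."""
        import hashlib
        import json

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
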
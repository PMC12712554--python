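"""Model assembly: areas, pathways and lesion switches.

The model consists of
* V1 -> V4 Layer 4 -> V4 Layer 2/3 (retinotopic, feedforward + pooling),
* an FEF cell cascade FEFv -> FEFvm -> FEFm seeded with a corollary
  discharge (CD) at the retinotopic saccade target,
* an intermediate combined map Xh converting the retinotopic FEFm
  activity into a head-centered CD signal (RBF coordinate transform),
* a head-centered attention-pointer stage holding the endogenous
  attention input (with a slow working-memory trace, so an established
  pointer briefly outlives its input),
* LIP, split into two combined retinotopic-x-eye-position parts gated by
  the CD signal (LIP CD) and by the proprioceptive eye-position signal
  (LIP PC), both driven by the attention pointer (plus task-specific V4
  input and an FEFvm enhancement at the saccade target), and
* two modulatory feedback pathways into V4 Layer 4: FEFvm -> V4 (phasic
  saccade-target attention) and LIP -> V4 (remapped attention pointers),
  each individually lesionable.

All stages that do not depend on the random bar stream (FEF cascade, Xh,
attention pointer) are simulated once per trial block and broadcast
across the block's batch axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import (
    EyeAxis,
    lateral_spread,
    Projection,
    embed_headcentered,
    euler_step,
    rbf_combine,
    rbf_readout_headcentered,
    rbf_readout_retinotopic,
    smooth_projection,
)
from .geometry import FieldGeometry, gaussian_blob
from .params import ParameterSet

__all__ = ["LesionConfig", "Model", "ModelState", "StepSignals", "build_model", "step_model", "lip_projection_to_v4"]


@dataclass(frozen=True)
class LesionConfig:
    """Pathway deactivation switches; each affects only its projection."""

    fef_to_v4_enabled: bool = True
    lip_to_v4_enabled: bool = True


@dataclass
class StepSignals:
    """Inputs to one synchronous update step.

    ``vis`` is the retinotopic visual image per trial ``(B, ny, nx)``;
    ``att`` the head-centered attention-pointer input ``(1, ny, nx)``;
    ``cd_drive`` the CD seed at the retinotopic ST ``(1, ny, nx)``;
    ``pc_eye`` the proprioceptive gain profile over the eye axis ``(ne,)``.
    """

    vis: np.ndarray
    att: np.ndarray
    cd_drive: np.ndarray
    pc_eye: np.ndarray


@dataclass
class ModelState:
    """All map activities at one time point (batch axis leading)."""

    v1: np.ndarray
    v4l4: np.ndarray
    v4l23: np.ndarray
    fefv: np.ndarray
    fefvm: np.ndarray
    fefm: np.ndarray
    xh: np.ndarray
    lip_cd: np.ndarray
    lip_pc: np.ndarray
    ptr: np.ndarray
    ptr_trace: np.ndarray
    t: float = 0.0

    def max_rate(self) -> float:
        return max(
            float(np.max(a))
            for a in (self.v1, self.v4l4, self.v4l23, self.fefv, self.fefvm, self.fefm, self.xh, self.lip_cd, self.lip_pc)
        )


@dataclass
class Model:
    """Built model: geometry, parameters, projection graph, lesions."""

    params: ParameterSet
    lesions: LesionConfig
    geometry: FieldGeometry
    eye_axis: EyeAxis
    projections: list[Projection]

    def initial_state(self, batch: int = 1) -> ModelState:
        ny, nx = self.geometry.shape
        ne = self.eye_axis.n
        f32 = np.float32
        zeros = lambda *shape: np.zeros(shape, dtype=f32)  # noqa: E731
        ny2, nx2 = (ny + 1) // 2, (nx + 1) // 2
        return ModelState(
            v1=zeros(batch, ny, nx),
            v4l4=zeros(batch, ny, nx),
            v4l23=zeros(batch, ny2, nx2),
            fefv=zeros(1, ny, nx),
            fefvm=zeros(1, ny, nx),
            fefm=zeros(1, ny, nx),
            xh=zeros(1, ny, nx, ne),
            lip_cd=zeros(batch, ny, nx, ne),
            lip_pc=zeros(batch, ny, nx, ne),
            ptr=zeros(1, ny, nx),
            ptr_trace=zeros(1, ny, nx),
            t=0.0,
        )

    def projection(self, source: str, target: str) -> Projection:
        for p in self.projections:
            if p.source == source and p.target == target:
                return p
        raise KeyError(f"no projection {source} -> {target}")


def build_model(
    params: ParameterSet | None = None,
    lesions: LesionConfig | None = None,
    geometry: FieldGeometry | None = None,
    eye_axis: EyeAxis | None = None,
) -> Model:
    """Assemble the projection graph of the model with lesion switches."""
    params = params or ParameterSet()
    params.validate()
    lesions = lesions or LesionConfig()
    geometry = geometry or FieldGeometry()
    eye_axis = eye_axis or EyeAxis(sigma=params.sigma_eye_axis)

    projections = [
        Projection("V1", "V4_L4", "driving", params.w_v1_v4),
        Projection("V4_L4", "V4_L23", "driving", params.w_v4_pool, kernel_sigma=params.sigma_pool),
        Projection("FEFv", "FEFvm", "driving", params.w_fefv_fefvm),
        Projection("FEFvm", "FEFm", "driving", params.w_fefvm_fefm),
        Projection("FEFvm", "V4_L4", "modulatory", params.g_fef_v4, kernel_sigma=params.sigma_fef_v4, enabled=lesions.fef_to_v4_enabled),
        Projection("FEFvm", "LIP", "modulatory", params.w_fefvm_lip),
        Projection("FEFm", "Xh", "driving", params.w_fefm_xh),
        Projection("Xh", "LIP_CD", "modulatory", 1.0),
        Projection("PC", "LIP_PC", "modulatory", 1.0),
        Projection("attention", "LIP_CD", "driving", params.w_att_lip),
        Projection("attention", "LIP_PC", "driving", params.w_att_lip),
        Projection("V4_L4", "LIP", "driving", params.w_v4_lip),
        Projection("LIP", "V4_L4", "modulatory", params.g_lip_v4, kernel_sigma=params.sigma_lip_v4, enabled=lesions.lip_to_v4_enabled),
    ]
    return Model(params=params, lesions=lesions, geometry=geometry, eye_axis=eye_axis, projections=projections)


def _cd_eye_profile(model: Model, cd_head: np.ndarray) -> np.ndarray:
    """Eye-axis gain carried by the head-centered CD map.

    The CD head-centered blob lies on the horizontal center line; its
    profile along x, sampled at the eye-axis nodes, gives the gain each
    combined-map eye slice receives (the CD encodes the future eye
    position).
    """
    iy0 = model.geometry.to_index(0.0, 0.0)[0]
    cols = [model.geometry.to_index(e, 0.0)[1] for e in model.eye_axis.values]
    return cd_head[:, iy0, cols]  # (1, ne)


def step_model(model: Model, state: ModelState, signals: StepSignals, dt: float | None = None) -> ModelState:
    """Advance all maps by one synchronous Euler step.

    Every target is computed from the source activities of the *current*
    state, then all maps are replaced at once (synchronous update).
    """
    p = model.params
    dt = p.dt if dt is None else dt
    sat = p.saturation
    eye_norm = model.eye_axis.norm()

    # --- feedforward visual chain ------------------------------------- #
    v1 = euler_step(state.v1, signals.vis, tau=p.tau_v1, dt=dt, saturation=sat)

    # --- FEF cascade (shared across the block) ------------------------- #
    fefv = euler_step(state.fefv, signals.cd_drive, tau=p.tau_fefv, dt=dt, saturation=sat)
    fefvm = euler_step(state.fefvm, p.w_fefv_fefvm * state.fefv, tau=p.tau_fefvm, dt=dt, saturation=sat)
    fefm = euler_step(state.fefm, p.w_fefvm_fefm * state.fefvm - p.theta_fefm, tau=p.tau_fefm, dt=dt, saturation=sat)

    # --- Xh: retinotopic FEFm combined with the PC eye signal ---------- #
    xh_drive = rbf_combine(p.w_fefm_xh * state.fefm, signals.pc_eye)
    xh = euler_step(state.xh, xh_drive, tau=p.tau_xh, dt=dt, saturation=sat)
    cd_head = rbf_readout_headcentered(state.xh, model.eye_axis, model.geometry) / eye_norm
    g_cd = _cd_eye_profile(model, cd_head)  # (1, ne)

    # --- attention pointer with working-memory loops ------------------- #
    supra = np.maximum(state.ptr - p.theta_ptr_trace, 0.0)
    trace_fb = lateral_spread(
        np.maximum(state.ptr_trace - p.theta_ptr_feedback, 0.0), p.sigma_ptr_spread, model.geometry
    )
    ptr_drive = signals.att + p.w_ptr_self * supra + p.w_ptr_trace * trace_fb
    ptr = euler_step(state.ptr, ptr_drive, tau=p.tau_ptr, dt=dt, saturation=sat)
    trace_drive = p.k_ptr_trace * supra
    ptr_trace = euler_step(state.ptr_trace, trace_drive, tau=p.tau_ptr_trace, dt=dt, saturation=p.ptr_trace_max)

    # --- LIP: combined maps gated by their eye-related signals --------- #
    att_comb = embed_headcentered(state.ptr, model.eye_axis, model.geometry)  # (1, ny, nx, ne)
    base_drive = (
        p.w_att_lip * att_comb
        + p.w_v4_lip * state.v4l4[..., None]
        + p.w_fefvm_lip * state.fefvm[..., None]
    )
    lip_cd = euler_step(state.lip_cd, base_drive * g_cd[:, None, None, :], tau=p.tau_lip, dt=dt, saturation=sat)
    lip_pc = euler_step(state.lip_pc, base_drive * signals.pc_eye, tau=p.tau_lip, dt=dt, saturation=sat)

    # --- modulatory feedback into V4 L4 -------------------------------- #
    mods: list[tuple[float, np.ndarray]] = []
    if model.lesions.fef_to_v4_enabled:
        fef_proj = smooth_projection(state.fefvm, p.sigma_fef_v4, model.geometry)
        mods.append((p.g_fef_v4, np.broadcast_to(fef_proj, state.v4l4.shape)))
    if model.lesions.lip_to_v4_enabled:
        lip_total = rbf_readout_retinotopic(state.lip_cd + state.lip_pc) / eye_norm
        lip_proj = smooth_projection(lip_total, p.sigma_lip_v4, model.geometry)
        mods.append((p.g_lip_v4, lip_proj))
    v4l4 = euler_step(state.v4l4, p.w_v1_v4 * state.v1, mods, tau=p.tau_v4l4, dt=dt, saturation=sat)

    pooled = smooth_projection(state.v4l4, p.sigma_pool, model.geometry)[:, ::2, ::2]
    v4l23 = euler_step(state.v4l23, p.w_v4_pool * pooled, tau=p.tau_v4l23, dt=dt, saturation=sat)

    return ModelState(
        v1=v1.astype(np.float32),
        v4l4=v4l4.astype(np.float32),
        v4l23=v4l23.astype(np.float32),
        fefv=fefv.astype(np.float32),
        fefvm=fefvm.astype(np.float32),
        fefm=fefm.astype(np.float32),
        xh=xh.astype(np.float32),
        lip_cd=lip_cd.astype(np.float32),
        lip_pc=lip_pc.astype(np.float32),
        ptr=ptr.astype(np.float32),
        ptr_trace=ptr_trace.astype(np.float32),
        t=state.t + dt,
    )


def lip_projection_to_v4(model: Model, state: ModelState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Separately attributable LIP->V4 gain contributions (CD, PC, total).

    Returned in V4's retinotopic frame, each smoothed by the projection
    kernel; the total equals the modulation V4 receives when the LIP
    pathway is intact.
    """
    eye_norm = model.eye_axis.norm()
    p = model.params
    from_cd = smooth_projection(rbf_readout_retinotopic(state.lip_cd) / eye_norm, p.sigma_lip_v4, model.geometry)
    from_pc = smooth_projection(rbf_readout_retinotopic(state.lip_pc) / eye_norm, p.sigma_lip_v4, model.geometry)
    return from_cd, from_pc, from_cd + from_pc
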
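# Methods

`saccatt` simulates how covert spatial attention in a model of visual
area V4 is updated around a saccadic eye movement, and replicates a
trans-saccadic spatiotopic attention experiment on the model: random
probe bars are flashed around a guided 5° saccade while an endogenous
attention pointer is held at a cued head-centered position, V4 responses
are mapped by reverse correlation, and the onset/offset of attentional
modulation is detected with a windowed significance rule.  This note
documents the model, its parameters, the synthetic protocol, the
numerical choices, and the limitations a user should know about.

## Model

All populations are rate-coded neural fields on a 40° × 30° grid at
1 neuron/degree (41 × 31 nodes, origin at the field center).  Each map
obeys the leaky rate equation

    tau * dr/dt = -r + F( drive * prod_i (1 + g_i * mod_i) )

integrated with explicit Euler steps at dt = 1 ms, where `F` is
piecewise-linear (rectified below 0, saturated at 1) and modulatory
inputs act as multiplicative gain fields: modulation without feedforward
drive produces no response.

**Visual pathway.** Probe bars are rendered as Gaussian blobs at their
head-centered position minus the current eye position (retinotopic
frame), drive V1, and feed V4 Layer 4; Layer 2/3 pools Layer 4 with a
Gaussian kernel and 2× spatial down-sampling.  All analyses read
Layer 4.

**FEF cascade.** A corollary-discharge (CD) seed — a sigmoidal build-up
at the retinotopic saccade target centered ~104 ms before saccade onset,
decaying after the movement — drives FEF visual cells, which drive
visuomovement cells (FEFvm), which drive movement cells (FEFm, with a
firing threshold).  FEFvm gain-modulates V4 around the saccade target
(phasic, ST-directed attention) and also enhances ST-encoding LIP
neurons.  The saccade target is set directly; target selection is not
modeled.

**Coordinate transform (Xh).** FEFm's retinotopic activity is combined
with the proprioceptive eye-position signal in a radial-basis-function
(RBF) map Xh whose nodes are tuned jointly to retinotopic position `x`
and eye position `e`; summing all nodes with `x + e = h` reads out the
CD in head-centered coordinates — the future eye position.

**Attention pointer.** The endogenous attention input is a head-centered
Gaussian at the cued position (AP) whose amplitude builds up with a fast
onset component (~25 ms) plus a slow consolidation component (~200 ms).
It feeds a pointer stage with two working-memory loops: a fast
self-excitation that ignites the pointer once it crosses a threshold,
and a slow trace (τ ≈ 60 ms) that integrates supra-threshold pointer
activity and feeds back (with a saturating ~1° lateral spread and a
disengagement threshold).  Consequences, which carry the fading-attention
results: a pointer switched off very early collapses almost immediately
(the trace never charged); one switched off ~100 ms before the saccade
outlives its input by several tens of ms and then collapses; one
switched off late enough is held indefinitely by the trace alone.

**LIP.** LIP is split into two combined retinotopic × eye-position RBF
maps distinguished by their gating signal.  Both receive the attention
pointer along head-centered diagonals (node `(x, e)` receives the
pointer at `x + e`), plus weak task-specific V4 input and the FEFvm ST
enhancement.  LIP-PC is gated by the proprioceptive (PC) eye-position
signal: a gain over the eye axis at the pre-saccadic eye position that
swaps — amplitude cross-fade, no intermediate positions — to the
post-saccadic position starting 60 ms after saccade end, completing in
90 ms.  LIP-CD is gated by the head-centered CD signal read out of Xh.
The retinotopic readout of both parts (eye-axis marginal, smoothed)
gain-modulates V4.  The resulting geometry: before the saccade LIP-PC
points at AP's retinotopic locus and LIP-CD at the remapped position
RAP = AP − saccade vector; after the saccade LIP-PC lingers at the now
irrelevant retinotopic locus until the PC update jumps it onto the
(new) AP locus, taking over from the fading CD pointer.

The eye axis is deliberately coarse (6 nodes, 5° spacing, horizontal
only): the task's saccade is purely horizontal and the two eye positions
involved (0°, 5°) lie on nodes.  Narrow eye tunings (σ = 1.2°) prevent
gain leakage between the pre- and post-saccadic slices, which would
otherwise create spurious remapped/lingering ghosts.

**Lesions.** The FEFvm→V4 and LIP→V4 gain projections can each be
disabled; disabling reproduces, bit for bit, the dynamics obtained by
removing that term from the update.

## Experimental protocol

One trial lasts 700 ms; the eye movement starts at 350 ms, from the
fixation point (0,0) to the saccade target (5,0), with a duration given
by an affine amplitude–duration main sequence D = 42 ms + 5 ms/deg · A
(67 ms at 5°) and a raised-cosine position profile.  The attention
position is above or below FP or ST (±5° vertical offset).  Probe bars
are flashed on the two horizontal lines through the possible APs
(y = ±5°), with integer-degree horizontal positions uniform over the
field width, onsets within ±300 ms of saccade onset (minimum 5 ms onset
spacing and ~8 ms mean spacing per side), durations uniform in 5–20 ms,
and a 4° minimum distance between concurrently visible same-side bars.
Everything is a pure function of (parameter set, seed); per-trial seeds
derive from the batch master seed by a fixed counter scheme.

## Analysis

Each bar's response is the mean rate, over the 20 ms window from bar
onset, of the V4 L4 neuron at the bar's retinotopic locus at onset.
A neuron/trial pair is AU if the neuron's pre-saccadic receptive field
covers the AP (within 1.5°) and its post-saccadic one does not; UA vice
versa; UU if either covers the vertically mirrored control position.
Because the model is mirror-symmetric about the horizontal meridian, the
mirror loci within the same trials are exact controls, which doubles the
sample efficiency relative to running separate control batches.
Responses are pooled per condition into contiguous 20 ms bins of bar
onset relative to saccade onset; the UU bin mean is subtracted from the
AU and UA bins (normalized activity).  Per bin, normalized activity is
tested for being greater than zero with a one-sided Welch two-sample
t-test of the condition samples against the UU samples (α = 0.05,
trials as sampling unit; the two-sample form accounts for the control's
own sampling noise — a one-sample test on mean-subtracted samples
inflates the false-positive rate of the window rule roughly twofold).
Scanning from trial start, the first bin opening three consecutive
non-significant windows is the "offset in AU"; the first bin opening
three consecutive significant windows is the "onset in UA"; if no
qualifying run exists the result is "none".

## Parameters

All constants live in `ParameterSet` (YAML-serialisable); the defaults
were chosen once, by forward reasoning about the required dynamics, and
calibrated so that the model reproduces the published time courses of
this task family (tonic UA onset ≈ −100 ms, AU offset ≈ +200 ms; the
fading-attention pattern −150 → −140, −100 → −20, −50/+50 → +200 with
preserved UA onsets except at −150).  The load-bearing ones:

| parameter | default | role |
|---|---|---|
| `tau_*` | 4–10 ms | map time constants (pointer 4, LIP 5, V4 L4 6) |
| `pc_update_delay` | 60 ms | PC update begins after saccade end |
| `pc_swap_duration` | 90 ms | raised-cosine amplitude swap → tonic AU offset ≈ +200 |
| `cd_rise_center/width` | 104 / 8 ms | CD build-up before onset → UA onset ≈ −100 |
| `cd_decay_tau` | 70 ms | CD persistence bridging to the PC handover |
| `att_amp_fast/slow`, `att_tau_fast/slow` | 0.5/0.3, 25/200 ms | pointer build-up; the slow component times trace charging |
| `w_ptr_self`, `theta_ptr_trace` | 1.9, 0.68 | fast ignition loop (must satisfy w·(1−θ) < θ so the loop alone cannot latch) |
| `k_ptr_trace`, `tau_ptr_trace`, `theta_ptr_feedback` | 3.9, 60 ms, 0.18 | slow trace: charge rate, decay, disengagement cliff |
| `g_lip_v4`, `g_fef_v4` | 1.6, 0.5 | modulatory gains into V4 |
| `bar_sigma`, `att_sigma` | 0.8°, 1.1° | stimulus/pointer widths (narrow enough that the AP, RAP and control loci at 5° separations do not cross-talk) |

Parameters of the neuron ODEs and connections are flagged
robustness-eligible (perturbed ±5% by the robustness harness, uniform
within the interval); input-signal parameters define the stimulation
itself and are held fixed.

## What the synthetic protocol does and does not emulate

The generator reproduces the task structure: geometry, timing, probe
statistics, the four APs, and the stochasticity across trials (bar
positions, onsets, durations).  Trial-to-trial response variability
arises entirely from the stimulus stream — there is no intrinsic neural
noise, no fixational eye movements, no adaptation, and no behavioral
state.  Real recordings would add Poisson-like spiking variability and
session nonstationarities; passing tests here show that the *mechanism*
(remapping via CD-gated pointers, lingering via the late PC update, and
their dependence on pointer persistence) produces the reported timing
signatures under the stated protocol, not that the quantitative gains
match cortex.

Two analysis-level artifacts are inherited from the method and worth
knowing: responses to probes flashed mid-saccade are smeared across the
retina, thinning and skewing the perisaccadic response samples (the
windowed t-tests there run slightly hot); and the detection rule's
change points are quantised to the 20 ms bin grid, so all timings carry
±1 bin resolution.

## Numerical choices

Explicit Euler at dt = 1 ms (all τ ≥ 4 ms; halving dt changes 700 ms
trajectories by < 1%).  Synchronous updates: every map advances from the
current state.  Maps are float32; stages that do not depend on the
random bar stream (FEF cascade, Xh, attention pointer) are simulated
once per trial block and broadcast across trials.  Peak extraction
breaks ties toward the lowest index; degenerate configurations (zero
presentation window, fp = st) yield empty streams / constant eye
position rather than errors.  Reduced scale defaults: batches of a few
hundred trials with the AP above FP (the UU control comes from the
mirror loci), versus 4000 uniform-AP trials in the full-scale study;
per-bin sample counts are then ~100–200, which sets the significance
floor the change-point timings are calibrated against.

## Known limitations

* The exact constants of the original study's supplementary tables were
  not available; the defaults here are this package's own
  parameterisation, validated against the published results rather than
  transcribed.  Quantities not pinned by those results (absolute rate
  scales, L2/3 pooling details) are only loosely constrained.
* The fading-attention discrimination (turnoff −100 vs −50) is a
  threshold phenomenon by construction; it is reproduced robustly at the
  default parameters but is not expected to survive large parameter
  excursions, and the ±5% robustness analysis deliberately covers only
  the tonic protocol, as in the study replicated.
* The FEF is modeled only as far as ST-directed phasic attention and the
  CD relay; no receptive-field remapping in FEF, no target selection,
  no V4→FEF projection, no decision or reward process.
* With the eye axis collapsed to the horizontal dimension, vertical
  saccades are out of scope.
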
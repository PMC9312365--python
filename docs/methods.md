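# Methods

This note documents the models, estimators, numerical choices and known
limitations of `cavehydro`. Units are cm-g-s on the kinematics/drag side
(the laboratory convention) and SI on the PIV and panel-flow side; every
interface documents which applies.

## Speed from centroid tracks

The tracker yields centroid positions at a fixed frame interval Δt
(50 Hz in the behavior sessions, 10 Hz when the PIV camera is active;
Δt is a property of the trajectory, never hard-coded). The per-component
speed at an interior sample averages the two adjacent absolute
displacements,

    v_n,x = (|x_{n+1} − x_n| + |x_n − x_{n−1}|) / (2Δt),

and the speed composes them in quadrature. The first and last samples
have no centered estimate and are dropped. Because the components use
absolute displacements, the estimator is translation- and
time-reversal-invariant and never exceeds the mean step speed; on
persistent headings it equals the two-step average speed, while sharp
turns bias it slightly low (≤ (Δθ)²/8 relatively for a turn of Δθ between
steps — negligible at 50 Hz for the turn rates simulated here).

## Wall distance and occupancy

"Distance to the closest wall" means the minimum distance to the four
vertical side walls; the floor and the free surface are excluded because
an 8 cm water column makes them uninformative about wall-following (a
six-plane variant is available). Centroids within 2% of a tank dimension
outside the volume are treated as tracking noise: clamped to the
boundary with a warning. Farther excursions raise an error naming the
sample. Occupancy summaries report, per time bin (default 30 min), the
fraction of samples with wall distance below a threshold expressed in
body lengths (default 0.25 BL) plus mean speed and normalized distance
and speed histograms; empty bins report missing values, not zeros.

## Burst/coast segmentation

The segmentation is deliberately simple and fully parameterized, since
intermittent-swimming boundaries admit no canonical definition: the
speed series is smoothed with a centered 0.2 s moving average, a burst
is a contiguous run of smoothed acceleration above 2 cm/s² lasting at
least 0.2 s, and the following coast extends until the speed falls below
0.2 cm/s or the next burst begins, with a 0.4 s minimum. On noiseless
constructed cycles the recovered boundaries sit within about half a
smoothing window of the construction; on 50-cycle synthetic sessions the
recovered mean coast and cycle durations match the drawn means to a few
milliseconds.

## Coasting drag coefficient

A gliding fish with straight body decelerates under quadratic drag.
With effective inertia m_eff = M + kρV (k the added-mass coefficient),

    m_eff du/dt = −(ρ/2) C_d A u²   ⇒   u(t) = u0 / (1 + β u0 t),
    β = C_d ρ A / (2 m_eff),

so reciprocal speed is linear in time and an ordinary least-squares fit
of 1/u on t yields C_d = slope · 2 m_eff/(ρA). Choices:

- **k = 0.045 by default.** The literature value adopted in the source
  study's text; the study's symbol table prints 0.45, an apparent
  typographical slip. The default is configurable and its use is
  recorded in every run report.
- **ρ = 991 kg/m³ by default**, the study's tabulated value (pure water
  at 17 °C is ≈ 998.8); kept so the arithmetic reproduces the study's
  worked numbers, and configurable.
- **Unweighted OLS** on 1/u vs t is the default (the plainest reading of
  "linear regression"); reciprocal-variance weighting (weights ∝ u²,
  optimal for multiplicative speed noise) is available.
- **Speed floor 0.2 cm/s**: 1/u amplifies noise as u → 0, so a trailing
  run of sub-floor samples is trimmed before fitting.
- A non-positive slope (non-decaying sequence) flags the result invalid
  instead of reporting a meaningless coefficient.
- The fit runs in cm-g-s internally (slope in cm⁻¹); an `units="si"`
  path accepts SI inputs and returns the identical dimensionless C_d.

With 5% multiplicative speed noise the estimator carries a small
positive bias of order noise² (≈ 0.2%), far below the Monte-Carlo spread
of a 65-glide batch.

Reynolds numbers are uL/ν with ν = 1.085 × 10⁻⁶ m²/s at 17 °C. Note
that u = 1.57 cm/s over one body length gives Re ≈ 1.24 × 10³, close to
but not exactly the rounded 1.28 × 10³ quoted in the source study (whose
exact ν and length scale are unstated).

## Laser-plane kinetic energy and sensing distance

Each PIV frame is a rectangular node grid with in-plane velocity
components; the plane kinetic energy is

    E_L = Σ_nodes ½ ρ h |v|² ds,

with sheet thickness h = 2 mm and trapezoid cell areas (interior nodes
weigh dy·dz, edges half, corners a quarter, so Σds equals the plane area
exactly). E_L is computed once per frame at the 5 Hz PIV cadence.

The head position is the tracked centroid advanced by BL/2 along the
displacement heading (no orientation data exists; a stationary fish
falls back to the centroid distance, flagged). For a transverse plane at
x = x_L only the x component matters, and distances are reported in BL.

"Increases abruptly" is operationalized as a two-threshold (Schmitt
trigger) onset detector, per sequence: the baseline mean μ and SD σ come
from the first 10 approach frames; a candidate onset is the first run of
≥ 2 frames above μ + 5σ; the event is accepted only if the excursion
also reaches a confirmation level μ + 20σ within that run, which makes
the timing robust to single near-threshold noise spikes. Because the
disturbance velocity amplitude grows smoothly from zero, the excess
energy grows quadratically, so √(E_L − μ) is locally linear in time; a
secant through the first confirmed frames extrapolated back to zero
refines the onset within the frame interval (clamped to the frames
bracketing the low-threshold crossing), removing most of the one-frame
quantization that a 5 Hz sequence would otherwise impose at approach
speeds of several cm/s. D_L and u_L are linearly interpolated at the
refined onset time. A sequence that never leaves baseline returns no
event — a valid outcome. All thresholds (window, z = 5, confirmation
z = 20, persistence) are configuration parameters; z = 5 is a design
choice, not an empirically derived value.

## Source-panel flow and the ΔCp stimulus

The volume-resolved RANS simulations of the original study are out of
scope; the package's flow stage is a 2-D mid-sagittal constant-strength
source-panel method — deliberately inviscid and non-lifting (symmetric
head-on onset flow, zero circulation, no Kutta condition). It is exactly
verifiable: on a 120-panel cylinder the computed Cp matches
1 − 4 sin²θ to machine precision, and the integrated pressure drag of
any smooth closed contour vanishes with refinement (d'Alembert). It
reproduces the qualitative head-region contrast between horned and
streamlined bodies; it does not, and is not meant to, reproduce a
viscous C_d(Re) curve.

Numerics: panels are the polygon edges, collocation at midpoints,
outward normals from the counterclockwise orientation (contours are
re-oriented on construction and checked simple via their polygon
representation); the influence matrix uses the standard local-frame
source formulas with ½ self-influence. Discrete source conservation
Σσᵢlᵢ is machine-zero on symmetric bodies and a small residual
(≲ 10⁻³ U·perimeter) on sharp-trailing-edge bodies, where the nearly
coincident trailing-edge panels degrade conditioning. Pressure follows
P = Cp·(ρ/2)U² (gauge, relative to free-stream static; Cp = 0 far
away), and drag integration uses F = −Σ Pᵢ (n̂ᵢ·x̂) lᵢ so pressure on
upstream-facing panels counts as positive drag. The reference area for
C_d is the projected frontal length per unit span for intrinsic 2-D
results and the specimen surface area when post-processing imported 3-D
surface-pressure fields.

Canal pores sit every 0.02 BL along the dorsal path — the vertex walk
from the snout (anterior-most vertex) to the tail along whichever side
has the greater mean height, a 2-D reduction of the supraorbital/
supratemporal/trunk canal layout. Cp at a pore is linearly interpolated
in arc length between panel midpoints; ΔCp is the exact adjacent-pore
difference (the telescoping identity ΣΔCp = Cp_last − Cp_first holds to
machine precision), and pores with s ≤ 0.3 BL are flagged as the head
region.

## Synthetic-data generator

The generator exists to close the loop: analyzing generated data must
recover the generating parameters within Monte-Carlo error. It emulates
the study conditions, not hydrodynamic reality:

- **Trajectories.** A two-state behavioral walk: wall-following bouts
  travel along the tank perimeter at a fixed sub-threshold offset
  (drawn uniformly in (0.1, 0.9) of the 0.25 BL threshold), roaming
  bouts are a persistent-heading walk steered away from the near-wall
  band, and transitions are continuous swims (no teleports, so the
  speed series is unpolluted). Bout dwell times are Gamma-distributed
  (shape 6, wall mean 10 s) — chosen short enough that an hour contains
  hundreds of renewal cycles and the realized occupancy concentrates
  tightly. The wall-state fraction is tuned to the occupancy target by
  bisection against a deterministic 30-minute calibration run at the
  session's own frame rate, because transit time through the near-wall
  band also counts as near-wall occupancy. The speed profile is an
  independent burst-and-coast sequence: burst durations N(0.81, 0.29²) s,
  coast durations N(2.15, 0.63²) s (truncated at 0.3/0.6 s), linear
  speed ramps during bursts at a drawn acceleration (N(5, 1) cm/s²,
  floored at 3 — a speed law, since the study describes tail-beat
  kinematics, not accelerations), and closed-form quadratic-drag decays
  during coasts. When a mean-speed target is given the whole profile is
  rescaled once so its time mean matches exactly; z is held at
  mid-depth. Depth excursions, glide curvature and tank-floor effects
  are not modeled, so passing recovery tests validates the estimators,
  not behavioral realism.
- **Coasting batches.** Initial speeds uniform in 4–10 cm/s, durations
  truncated-normal around 2.2 s (the observed series lengths),
  10 Hz sampling, multiplicative Gaussian speed noise (default SD 0.05
  — a plausible magnitude for video-derived speeds; the study reports
  no noise level). Truth manifests record C_d, β and every u0.
- **PIV sequences.** Quiescent frames are i.i.d. Gaussian velocity noise
  (SD 5 × 10⁻⁴ m/s per component on a 17 × 17 grid over 8 × 8 cm). Once
  the head comes within the onset distance, a spatially Gaussian jet
  (width 1.2 cm, amplitude 0.02 m/s — set so stage-2 E_L exceeds
  baseline by far more than 20 baseline SDs) ramps linearly over 0.6 s,
  then decays exponentially (0.5 s) after the fish passes — the
  three-stage approach/enter/exit pattern. The start distance is
  jittered by up to one frame's travel so the trigger moment is not
  aligned with the frame clock. The disturbance model is an invention;
  the study describes the stages only qualitatively.
- **Contours.** The streamlined family is a symmetric four-digit-style
  thickness profile (closed trailing edge, default thickness ratio 0.13,
  cosine vertex spacing concentrating resolution at the nose); the
  horned family adds a Gaussian dorsal bump (default height 0.08 BL at
  0.22 BL, width 0.06 BL) tapered to zero at both ends, which keeps the
  curve simple by construction. A horn of height zero reduces exactly to
  the streamlined family.

All generators are pure functions of (parameters, seed); truth manifests
are emitted beside the data and never consumed by analyzers.

## Problem sizes

The validation suite uses the study's own batch sizes where they exist —
65 coasting glides, 21 PIV approaches, 50 burst-and-coast cycles,
one-hour behavior sessions at 50 Hz — and 120–240 panels for the flow
oracle, where the cylinder error is already at machine precision.

## Known limitations

- The panel method is inviscid: no boundary layers, no separation, no
  wake, hence no meaningful absolute drag for a real fish and no
  Re-dependence. ΔCp contrasts are qualitative.
- The pore path is a 2-D dorsal reduction; real canal pores have 3-D
  positions that are only approximately known even in the source study.
- The head-position estimate assumes the body axis aligns with the
  displacement heading; a fish drifting sideways would bias D_L.
- The two-state behavioral walk reproduces occupancy and speed
  statistics, not the geometry of real exploratory paths.
- Trajectory generation relies on per-sample iteration; sessions much
  longer than a few hours at 50 Hz become sluggish in pure Python.
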
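# Methods

## Model

The right lower limb is modeled as a serial kinematic chain of three
rigid segments — femur, tibia, foot — linked by three revolute joints
(hip, knee, ankle) that all rotate about the lateral axis **z**, so the
chain moves in the sagittal **x–y** plane: 3 degrees of freedom in
total. The global frame F0 sits at the hip with **x** anterior, **y**
cranial, **z** lateral-right; in the anatomical posture (all joint
angles zero) every local frame is aligned with F0 and the leg hangs
straight down.

Default geometry corresponds to a 1.65 m adult: femur 0.37 m, tibia
0.38 m, lateral-malleolus height 0.08 m and malleolus-to-hallux
(toe) distance 0.25 m. Segment offsets are expressed in the parent
frame: `p₂ = (0, −0.37, 0)`, `p₃ = (0, −0.38, 0)` (down), toe offset
`p_g = (0.25, −0.08, 0)` (forward and down). The toe frame carries no
extra rotation — it follows the ankle's orientation.

Each joint i carries the half-angle rotation vector `Φᵢ = (θᵢ/2)·ẑ`
(radians); the rigid transform from its parent frame is the unit dual
quaternion

    q̲ᵢ = (1 + ε·pᵢ/2)·e^{Φᵢ},   ε² = 0.

Forward kinematics is the ordered dual-quaternion product
`q̲_W = q̲₁ q̲₂ q̲₃ q̲_g`; each landmark's **posture** — the 6-vector
of world position (m) and rotation-vector orientation (rad) — is
extracted as `p = 2 q_d q_p*` and `o = 2 ln(q_p)`.

Sign conventions: positive angle = counter-clockwise about +z
(right-hand rule), so hip flexion is positive, knee flexion negative,
ankle dorsiflexion positive — consistent with signed joint limits such
as a knee range of [−50.4°, −5.6°] in toe-walking. Joint angles cross
the API boundary in degrees; internally everything is radians.

## Quaternion exp/log and the small-angle singularity

`exp(Φ) = cos|Φ| + (sin|Φ|/|Φ|)·Φ` and its inverse both contain 0/0
ratios at the identity rotation. Below `|Φ| < 1e-4` (respectively
`|q_v| < 1e-4` for the log) the ratios are replaced by their truncated
Taylor series, `1 − x²/6 + x⁴/120` for the sinc and `1 + x²/6 + 7x⁴/360`
for `x/sin x`. At the switch point the two branches agree to ~1e-16, so
the maps are numerically continuous through the crossover; the test
suite checks a band on both sides. The log uses
`θ = 2·atan2(|q_v|, q₀)` wrapped to the branch θ ∈ (−π, π], which keeps
negative rotations distinguishable from positive ones (an `arccos`
formulation would fold them together). `q` and `−q` encode the same
rotation; the log operates on its input as given and callers needing
continuity handle hemisphere alignment — shipped gait models never
approach ±180°, so this never triggers in practice.

## Inverse kinematics

Per sample, the damped least squares (DLS) iteration is

    J    ← ∂ξ/∂Φ at the current configuration        (6 × 9)
    Δξ   ← α (ζ − ξ)
    ΔΦ   ← Jᵀ (J Jᵀ + γ² I)⁻¹ Δξ
    Φ    ← clamp(Φ + ΔΦ)
    ξ    ← f(Φ)

terminated when `|ζ − ξ| ≤ ε` or after N iterations. The error norm is
the plain Euclidean norm of the 6-vector, metres and radians mixed; a
diagonal weighting hook exists but defaults to identity. Tunables, with
defaults per gait type:

| parameter | normal | toe-walking | heel-walking | meaning |
|---|---|---|---|---|
| α | 0.6992 | 0.7334 | 0.7301 | step-size factor in (0,1) |
| γ | 0.0579 | 0.0608 | 0.0579 | damping constant in (0,1) |
| ε | 1e-6 | 1e-6 | 1e-6 | posture-error threshold |
| N | 56 | 56 | 56 | iteration cap per sample |
| limits (deg) | ±180 | hip [−6.4, 33.6], knee [−50.4, −5.6], ankle [−32.3, −7.6] | hip [7.5, 34.3], knee [−25.8, −8.2], ankle [9, 19.2] | range of motion |
| initial θ (deg) | (1, −5, −1) | (1, −5, 1) | (32, −5, 12) | warm-up configuration |

The initial configurations keep the knee in slight flexion (−5°),
which selects the knee-forward solution branch. The toe-walking initial
knee angle (−5°) sits marginally outside that gait's knee range
([−50.4°, −5.6°]); the solver therefore clamps the initial
configuration into the active limits before the first iteration, so the
documented defaults remain directly usable.

**Jacobian.** The default is central finite differences with step
h = 1e-6 rad on each of the nine rotation-vector components — truncation
plus rounding error is ~1e-10, far below what the ε = 1e-6 iteration can
see. An analytic Jacobian is also provided, built from SO(3)
left-Jacobian factors: a perturbation dΦᵢ tilts everything distal of
joint i by `dθ_W = R_{W,i−1} · J_l(2Φᵢ) · 2 dΦᵢ`; position rows follow
from `dp = dθ_W × (p_g − p_i)` and orientation rows from
`J_l⁻¹(o_W) · dθ_W`. The two agree entrywise to better than 1e-9 on
random configurations (tested at 1e-6), including non-planar rotation
vectors.

**Damping.** The largest singular value of the damped pseudo-inverse is
1/(2γ), so every step obeys `‖ΔΦ‖ ≤ ‖Δξ‖/(2γ)` — the solver cannot blow
up at singular configurations or on unreachable targets; it simply stops
at the iteration cap with a finite, limit-respecting configuration and
`converged=False`.

**Clamping.** The signed planar angle is recovered as `θᵢ = 2Φᵢ,z`
(the planar axis carries the sign, so negative limits compare
correctly — a magnitude-only reading would make a negative knee bound
meaningless), clipped into `[θ_min, θ_max]` and rebuilt as
`Φᵢ = (θ/2)ẑ`. In-limit angles are returned bit-identical. Off-plane
components (Φᵢ,x, Φᵢ,y) are part of the 6×9 Jacobian and the DLS
update, but are projected to zero by the clamp: for planar targets they
receive only finite-difference noise, and the projection prevents that
noise from accumulating.

**Accumulation and warm start.** The clamped configuration is the one
accumulated across iterations (it is also the returned quantity).
When tracking a trajectory, sample 0 starts from the per-gait initial
configuration and each later sample starts from the previous sample's
solution; on smooth gait curves this keeps per-sample iteration counts
near 10 instead of restarting the search each sample. Warm starting can
be disabled.

## Synthetic gait trajectories

No captured joint-angle dataset ships with the package. Each joint's
curve over one cycle (0–100%) is a two-harmonic Fourier series
`θ_j(t) = mean_j + Σ_h A_{jh} cos(2πh t/100 + φ_{jh})` — smooth (C∞),
exactly periodic, and validated on a dense grid against the labeled gait
type's range of motion (a violating spec is rejected). The three
shipped presets were chosen once as physiologically plausible sagittal
ranges: normal gait hip ≈ [−11°, 31°], knee ≈ [−59°, −1°], ankle ≈
[−18°, 13°]; the toe- and heel-walking presets are confined to their
restricted ranges while spanning at least 60% of each joint's interval
so the clamping machinery is genuinely exercised. The canonical
sampling is 101 points per cycle; 60 Hz is carried as metadata only.
Optional seeded phase jitter exists for sensitivity studies and is off
by default, so all presets are fully deterministic.

What the generator does *not* emulate: stance/swing event structure,
stride-to-stride variability, measurement noise, soft-tissue artifact,
or any particular subject's waveform. Passing round-trip tests on these
curves therefore demonstrates solver correctness and conditioning on
smooth, limit-respecting trajectories — not robustness to noisy capture
data.

## Evaluation

The round-trip protocol (FK1 → IK → FK2) reports RMS errors per joint
angle (deg), per landmark position (knee, ankle, toe; m) and per
segment orientation about z (femur, tibia, foot; deg — the only
rotation the planar model admits), plus per-sample iteration counts and
the mean final error norm. Wall-clock times are logged for interest but
are hardware-dependent and never asserted on.

The homogeneous-matrix baseline recomputes the identical chain contract
with 4×4 transform composition (rotation matrices via
`scipy.spatial.transform.Rotation`), sharing no code with the
dual-quaternion kernel. It serves two roles: an independent
forward-kinematics oracle (agreement within 1e-10 over random
configurations), and the alternative kernel inside the same DLS stepper
for the representation comparison — only the FK kernel changes, with the
baseline given a higher iteration cap (default 100), so any difference
traces to the iteration path, not the kinematics.

`data_resolution` implements the capture-resolution estimator used to
justify ε: sort the samples, drop duplicates, and take the minimum
difference between adjacent distinct values.

## Numerical choices and limitations

- Unit tolerance 1e-9 for quaternion/dual-quaternion validation; drift
  over hundreds of multiplications stays orders of magnitude below it,
  and no automatic re-normalization is performed.
- Problem sizes: the canonical experiment is one 101-sample cycle; test
  suites use 1000 random configurations for FK equivalence, 100 for
  Jacobian agreement and parameter recovery, chains of 100 for unit
  closure.
- **Straight-knee singularity.** When the knee approaches full
  extension the planar Jacobian loses rank: the smallest singular value
  of the effective 3×3 system falls below 0.02 near θ₂ ≈ −3°, so a
  converged posture error of 1e-6 can still leave joint-angle errors of
  several 1e-3 degrees, and convergence itself slows (damping limits the
  step exactly where the linearization is weakest). The
  parameter-recovery guarantee (< 1e-3° at ε = 1e-6) therefore applies
  to flexed-knee configurations (knee ≤ −25°, where the measured minimum
  singular value ≥ 0.13 makes the bound provable); near-straight knees
  are accurate in *posture* but intrinsically ill-conditioned in
  *angles*. This is a property of position-based IK on this chain, not
  of the solver.
- Hip position is pinned at the origin by construction, so position
  RMSEs are reported for knee, ankle and toe only.
- The solver estimates angles from the toe posture alone; no null-space
  or secondary-task terms, no joint weighting or coupling, and no
  automatic tuning of α, γ (they are configuration).
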
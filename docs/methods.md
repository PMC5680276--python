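# Methods

`flagbeat` analyses the planar flagellar beat of tethered human sperm
and the temporal symmetry breaking that makes the cell rotate.  This
note records the models, the estimators, the numerical choices, and
what the synthetic data do and do not establish about real recordings.

## The two-harmonic beat model

The central object is the curvature kymograph C(s, t): signed local
curvature (µm⁻¹, counter-clockwise positive) versus arclength s (µm,
measured from the first tracked point) and time.  The beat is modelled
as a superposition of a fundamental traveling wave and its second
harmonic,

    C(s, t) = C0 + C1·sin(ks − ω0·t) + C2·sin(ks − 2ω0·t + φ),

with wave number k = 2π/λ, fundamental angular frequency ω0 and a
static offset C0 (the intrinsic curvature).  A single-frequency planar
beat is its own mirror image after half a period, C(s, t) = −C(s, t+τ/2);
the second harmonic breaks this *temporal* mirror symmetry without
making any instantaneous shape spatially asymmetric.  The steering-
relevant combination is the second-harmonic intensity C2·sin φ.

Default parameters mirror the tethered-sperm recordings the package is
built around: beat frequency ω0/2π = 20 Hz, λ = 40 µm, C1 = 0.1 µm⁻¹,
C2/C1 = 0.1–0.3, Δs = 0.9 µm over ~30 arclength points, 500 frames/s,
records of 10–30 s.

## Synthetic data

The generator module produces, with full ground truth: curvature
fields (closed form, exact at the grid nodes when noise-free), tracked
point series of a tethered cell (tangent-angle integration of the
curvature, rigid rotation about the pivot by 2π∫Ω dt, optional
beat-frequency body wobble of 0.05 rad emulating head recoil, per-frame
tail dropout of 0–3 points emulating tracked-length variation), and
rendered image stacks (Gaussian line-spread ridge of SD 0.45 µm at
0.2 µm/px, a 2.5 × 1.5 µm Gaussian head blob, additive sensor noise).

Slow variation of the second harmonic — the experimental rotation
velocity changes smoothly over seconds — is modelled as mean-reverting
(Ornstein–Uhlenbeck) drift of C2(t) and φ(t) with a 2 s correlation
time, stationary SDs of 30% (relative, C2) and 0.8 rad (φ), lightly
smoothed.  These drift statistics are stand-ins chosen to look like
published rotation traces; no measured distribution exists for them.

What the synthetic data do **not** emulate: out-of-plane motion and
rolling, illumination gradients and vignetting, head-shape variability,
pixel-correlated camera noise, and any real covariation between beat
frequency, amplitude and rotation.  A passing pipeline therefore
demonstrates estimator correctness under the stated model, not
robustness to every property of dark-field video.

## Tracking

Per frame: (1) binarization by lowering a threshold from the 99.5th
intensity percentile in ×0.98 steps until the foreground area reaches
the expected cell area (tolerance 15%) and the skeleton reaches the
expected coarse length; (2) head localization by a morphological
opening (1 µm disk) and an ellipse fit to the remaining blob — a circle
(axes within 5%) has undefined orientation and is flagged; (3) the
skeleton outside 1.15× the head ellipse, pruned of spurs shorter than
2 µm, must form a single path (otherwise "ambiguous topology"), ordered
from the head-adjacent endpoint; (4) sub-pixel refinement by the
intensity-weighted centroid along the local normal (±2 px); (5) the
arclength origin is re-anchored where the path first reaches 7 µm from
the head centre — the raw skeleton endpoint jitters with the beat, and
an origin sliding along the filament aliases fundamental motion into
the second-harmonic band (this inflated C2/C1 by ~20% before
anchoring); (6) resampling at Δs = 0.9 µm and a light Savitzky–Golay
smoothing (window 7, order 2) along arclength; (7) the common-window
rule: only the arclength tracked in every frame is analysed.

On default-noise synthetic scenes the tracker recovers the midline with
~0.03 µm RMSE and the downstream C2/C1 within ~5%.

## Kinematics

Curvature is the signed inverse circumradius of contiguous point
triples (Menger curvature; collinear triples give exactly 0, endpoints
carry no value).  The rotation velocity Ω(t) is the derivative of the
unwrapped pivot-to-first-point angle after Gaussian filtering; the
filter "width" is interpreted as the SD (1 s default, truncated at
±3 SD) — whether width meant SD or FWHM is not pinned down anywhere,
and the choice is exposed in the API.  The mirror-symmetry defect
‖C(s,t) + C(s,t+τ/2)‖₂ / 2‖C‖₂ uses an exact Fourier time shift
(an integer-frame shift would alias whenever τ/2 is off the grid) and
equals C2/√(C1²+C2²) for an offset-free two-harmonic wave.

## Principal beat modes

Modes Γₙ(s) are eigenvectors of the non-standardized arclength
covariance ⟨C(s,t)C(s′,t)⟩_t without mean removal (the time-averaged
curvature is ≈0).  All inner products use trapezoid quadrature on the
s grid, making the decomposition exactly complete on the grid and the
eigenvalue sum equal to the integrated time-variance.  Significance is
judged per rank against 95th percentiles of eigenvalues of δ-correlated
Gaussian curvature matched to the total field variance (50 replicates
by default); counting stops at the first non-significant rank.  The
limit-cycle phase is α = arctan(χ₂/χ₁), unwrapped; the conditional
phase velocity ω(α) uses 36 bins with a 20-sample minimum.

For a two-harmonic beat the 2ω0 component lives in the *same* spatial
mode pair as the fundamental (both are sin ks/cos ks), so ω(α) is
modulated once per cycle, ω(α) ≈ ω0·(1 + r·cos(α−φ)) with r = C2/C1:
one minimum and one maximum per beat, with min/max ratio (1−r)/(1+r) —
1:2 at r ≈ 0.3, matching the 20 vs 40 Hz extremes of real beats.

Cross-cell mode alignment rescales arclength to wavelength units,
interpolates to the common grid, and finds the optimal orthogonal 2×2
transform (1° rotation grid with reflection, refined by the closed-form
Procrustes solution) plus a least-squares amplitude scale compensating
for the differing normalization spans.

## Harmonic estimation

A sliding rectangular window (250 frames, step 30) locates the dominant
spectral peak in a 10–35 Hz band; the peak frequency is refined by
Jacobsen's complex three-bin estimator (nearly unbiased for rectangular
windows; magnitude-parabola interpolation left ~0.5 Hz bias), and the
complex amplitudes at ω0 and 2ω0 are re-estimated by least squares at
the refined frequency, immune to scalloping and to leakage between the
two components.  Windows whose peak is below 4× the median in-band
magnitude are masked.

The phase φ is reported relative to twice the fundamental phase —
the only shift-invariant combination at a single probe.  Because the
two harmonics travel at different phase velocities, this raw quantity
equals the traveling-wave φ minus k·s0; supplying the wave number
restores the waveform convention, which is how generator round trips
close.  On real data k is not known a priori and the unknown constant
is absorbed, exactly as in the analysis convention, by the fitted
offset φ0.

The steering correlation R between Ω/ω0 and C2·sin(φ+φ0) is computed
about zero (no second harmonic ⇒ no rotation), with the denominator
⟨I²⟩ (the published form of the correlation squares the denominator term
once more, which would break |R| ≤ 1 and is treated as a typographical
slip).  Both intensity quadratures are passed through the same 1-s
Gaussian as the rotation estimate before correlating: an unmatched
bandwidth biases the R-maximizing φ0 by several tenths of a radian.
φ0 — one constant per recording — is found by a 720-point grid plus
bounded refinement.

## Resistive-force theory

With anisotropic local drag (ξ∥ = 0.69 fN·s·µm⁻², ξ⊥/ξ∥ = 1.81) the
cycle-averaged transverse force density of the small-amplitude
two-harmonic wave is f_y = ω0k²(ξ⊥−ξ∥)y1²y2·cos(kx−φ), verified here
against direct quadrature to 10⁻³ relative.  Closed-form rotation
velocities implemented: the λ→L second-harmonic law
Ω = −ω0·(3L³/4(2π)⁴)·((ξ⊥−ξ∥)/ξ⊥)·C1²C2·sin φ and its intrinsic-
curvature companion Ω = ω0·(L³/(2π)⁶)·((ξ⊥−ξ∥)/ξ⊥)·C1²C0·π(π²−3);
for equal |C0| and |C2| the two differ only by the coefficient ratio
4π(π²−3)/(3(2π)²) ≈ 0.73.

The independent oracle is the exact overdamped dynamics of a tethered
filament with prescribed curvature: the rigid-rotation degree of
freedom closes by instantaneous torque balance,
γ̇(t) = T_beat(t)/ξ_rot(t), with ξ_rot(t) the rotational drag of the
current shape, and Ω = ⟨γ̇⟩/2π.  Its correctness is established by
rebuilding the lab-frame motion and verifying that the net
hydrodynamic torque about the pivot vanishes (3×10⁻⁵ relative).

Two findings from this oracle are worth stating plainly.  First, the
published λ→L closed form is a genuine asymptotic approximation: at
λ = L the exact response is Ω ∝ C1²C2·sin(φ+δ) with an amplitude ~1.5×
the published coefficient and a phase shift δ ≈ 1.75 rad relative to the
published −sin φ; the same kind of derivation offset is why a fitted
constant φ0 is needed when correlating the closed form with data.  The
package keeps both, and the acceptance comparison between them reports
the measured ratio rather than forcing agreement.  Second, the exact
tethered dynamics rotates even under *isotropic* drag — the tether
exerts an external force, so the force-free argument that propulsion
requires drag anisotropy does not apply; the rotation is then the pure
shape-space (zero drag-angular-momentum) effect and is independent of
the drag magnitude.  The closed forms, by contrast, are strictly
proportional to ξ⊥−ξ∥.

## Active-filament simulation

The filament is N = 50 rigid segments (Δs = L/N ≤ 1 µm) in tangent-
angle coordinates, so inextensibility is exact.  Bending elasticity κ
(1.9 nN·µm² default) acts at the joints; the active drive
T(s,t) = T0 + T1·sin(ks−ω0t) + T2·sin(ks−2ω0t+ψ) is applied as
equal-and-opposite moment couples at the joints — i.e. T is the
internal active bending moment — which keeps the drive internally
balanced (zero net force and torque).  Local RFT drag per segment
assembles the configuration-dependent generalized drag metric R(q);
the dynamics R(q)q̇ = F_el + F_act is stepped semi-implicitly (implicit
in the stiff linear bending term, explicit in geometry and activity),
with Δt = period/900 by default; a joint angle exceeding π/2 or a
runaway curvature aborts with the violated bound.  Tethering pins the
proximal node, with rotation loaded by the rotational drag of a 2.5 µm
sphere in the recording medium (≈275 fN·µm·s; the head drag value used
in the original fits is not published); free swimming adds the base
position with the corresponding translational drag (≈33 fN·s·µm⁻¹).

Two numerical points matter at these parameters.  The large-scale
elastic relaxation times ξ⊥L⁴/κ reach tens of seconds, far beyond any
affordable run, so (1) simulations start from the closed-form periodic
orbit of the dynamics linearized about the straight configuration,
which removes the transient at its source, and (2) the rotation
measurement optionally removes the residual single-mode tail by
geometric (Aitken) extrapolation of per-period increments of the
segment-averaged body angle (period blocks contain an exact integer
number of saved samples, otherwise beat wobble leaks into the
estimate).  Ratios, linearity in T* = T2/T1, and the sinusoidal ψ
dependence are insensitive to the remaining bias; absolute Ω at 3 s
still carries a multiplicative offset of tens of percent relative to a
10 s run.

Energetics: dissipation ⟨ξ⊥v⊥² + ξ∥v∥²⟩ per unit length at the
segments, generated power ⟨T·∂ₜC⟩ per unit length at the joints (the
exact original definition is unpublished; this choice makes motor
output positive and closes the budget), head dissipation separately.
Global balance generated = dissipated holds within ~0.4% at the default
step (the residual is the O(Δt) numerical dissipation of the implicit
bending step).  The dissipated-power profile is strongly tip-weighted;
the generated-power profile peaks in the interior.

With the published drive amplitudes the emergent mid-flagellum
curvature amplitude is small (C1 ≈ 0.01 µm⁻¹ at mid-length — the
continuum response T1k⁴/√(κ²k⁸+ξ²ω0²) — with a large thin boundary
layer at the free tip where the elastic moment must cancel the active
one, C ≈ T1/κ).  The emergent beat is therefore more tip-weighted than
a real flagellar beat; how the original drive realization produced
experiment-scale mid-flagellum amplitudes from the same published numbers
is not reconstructible from the available description.  The cross-module
check — closed-form steering law evaluated with the emergent mid-probe
C1, C2, φ versus the simulated rotation — agrees in sign and to a
factor ≈1.7 once the simulation is run to convergence (15 s; shorter
runs inflate |Ω| through the residual slow transient).

Free-swimming paths are summarized by per-beat-period block means of
the head position and the circumcircle curvature of consecutive block
triples; a symmetric drive gives path curvature at the numerical floor,
a constant ψ a consistently signed circular arc, as expected from
quasi-static steering.

## Problem sizes used

Defaults were chosen so the full test suite and the acceptance script
each run in minutes on one core: 10–30 s synthetic records (500 fps,
30–40 arclength points), 50-replicate significance nulls, 3 s
simulations (N = 50, 900 steps/period) with 30 measured periods,
500-frame rendered scenes at 512×512 px.

## Known limitations

- Strictly planar: no torsion, rolling, or 3D waveforms.
- Local RFT only: no wall effects or nonlocal hydrodynamics, no
  buckling mechanics.
- The drive realization in the simulator (internal moment per joint)
  is one defensible reading of an under-specified model; emergent
  amplitudes at the published drive values are tip-weighted and small
  at mid-flagellum (see above).
- Harmonic drift statistics of the generator are plausible stand-ins,
  not fits to measured distributions.
- The significance null shares only the variance with the data
  (δ-correlated in s and t); correlated tracking noise would need a
  structured null.
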
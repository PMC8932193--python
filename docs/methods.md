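# Methods

This note records the models, numerical choices and validation design
behind `aortawss`, and what the synthetic experiments do and do not
demonstrate about real 4D flow data.

## Phantom flow model

Pulsatile laminar flow in a rigid circular tube is described exactly by
the Womersley solution.  The generator is parameterized by the
flow-rate harmonics Q(t) = Re[Σₖ Qₖ e^{ikωt}] (ω = 2π/T) rather than by
the pressure gradient, because segment flow rate is the quantity a 4D
flow study observes.  The k = 0 term produces the steady Poiseuille
profile u₀(r) = 2Q₀/(πR²)(1 − r²/R²); each k ≥ 1 term is the Bessel
mode

    uₖ(r) = Qₖ/(πR²) · (1 − J₀(Λ r/R)/J₀(Λ)) / (1 − 2J₁(Λ)/(Λ J₀(Λ))),
    Λ = i^{3/2} α,   α = R √(kω/ν),

normalized so the mode's cross-sectional flux is exactly Qₖ e^{ikωt}.
The signed wall shear follows analytically: τ₀ = 4μQ₀/(πR³) plus each
mode's complex wall gradient.  TAWSS/OSI/RRT ground truth comes from
periodic quadrature of τ_w(t) at 256+ samples, treating τ_w as a 1-D
vector along the axis.

Aneurysms are modelled as Gaussian dilations of the wall radius —
axisymmetric ("fusiform") or one-sided ("saccular").  Inside a bulge
the profile is evaluated against the local boundary radius and scaled
by R²/⟨R_b²⟩ so the flux is conserved; the analytic truth is only
claimed on the straight part at least two bulge widths from the bulge
center.

### Rasterization and corruption

Voxel velocity equals the analytic velocity at the voxel center, zero
outside the lumen; no partial-volume averaging is simulated.  Defaults
mirror a whole-aorta protocol: 2.5 mm isotropic voxels, 40 timeframes
per cycle, VENC 150 cm/s, lumen wide enough for ≥ 8 voxels across the
diameter (the accepted minimum for image-based WSS).  Corruption is
applied in the order noise → wrap → offset:

* Gaussian velocity noise (default SD 5 cm/s ≈ 3% of VENC, a typical
  phase-contrast noise level) added to lumen and static-tissue voxels;
* a single phase wrap, v → v − sign(v)·2·VENC where |v| > VENC
  (velocities beyond 3·VENC would wrap twice and are rejected);
* a smooth polynomial offset field (total degree ≤ 4) added everywhere,
  standing in for residual eddy-current phase errors.

The magnitudes of these artifacts are calibration choices — the study
protocol they emulate does not publish its noise or offset levels.
All randomness derives from one integer seed; identical spec and seed
give bit-identical output.

## Preprocessing

**Phase unwrap.**  Each velocity component is compared with the median
of its 3×3×3×3 spatio-temporal neighborhood (center excluded, periodic
in time).  A voxel disagreeing by more than VENC is shifted by the
±2·VENC that minimizes the disagreement; voxels still beyond VENC after
one shift are left unchanged and counted.  The method assumes wraps are
locally sparse — the realistic regime where VENC is set near the peak
velocity.  When a large connected region aliases together (VENC far
below peak), the local median itself is wrapped and the correction
cannot recover it; multi-wrap or region-growing unwrapping is out of
scope.

**Background offset.**  A 3-D polynomial (default total degree 4, on
coordinates centered and scaled to the grid bounding box for
conditioning) is fit to the temporal-mean velocity of static-tissue
voxels by weighted least squares and subtracted everywhere.  The
weights 1/(ε + temporal variance), ε = 10⁻³ (cm/s)², down-weight
voxels contaminated by pulsatile signal; the weighting scheme is a
design choice, exposed as a parameter.  On noise-free phantoms the
injected coefficients are recovered to ~10⁻¹² relative because fit and
injection share the same (full-rank) basis.

## Surface, centerline, partition

The lumen surface is the 0.5 isosurface of the binary mask after a
mild Gaussian pre-smoothing of σ = 0.5 voxel.  Meshing binary data
directly overestimates area by ~9% (staircase bias); σ = 0.5 reduces a
digital sphere's area error to ~4% while keeping nodes within half a
voxel of the boundary.  Stronger smoothing (σ ≈ 1) halves the area
error but pulls nodes measurably inside the lumen, which biases the
wall-shear sampling and destroys the estimator's convergence under
grid refinement — so only the minimal amount is applied.  Outward
orientation is verified per node against the interpolated mask; node
area is one third of the incident triangle areas.

The centerline is the Dijkstra shortest path between two seed points
on the 26-connected lumen voxel graph with edge cost proportional to
1/d² (d = Euclidean distance to the wall), smoothed with a 5-point
moving average and resampled uniformly at ~1 mm, symmetrically in the
endpoints so swapping the seeds exactly reverses the polyline.

Five landmarks (aortic valve, brachiocephalic trunk, left subclavian,
renal arteries, iliac bifurcation) projected onto the centerline define
the segment boundaries: AAo ends at the brachiocephalic projection; the
arch extends 20 mm past the left subclavian; the DAo ends midway
between the arch end and the renals; the SAA ends at the renals; the
IAA at the iliac bifurcation.  Mesh nodes take the segment of their
nearest centerline point; a node exactly on a boundary goes to the
distal segment.  Cross-sections are evaluated every 2 mm on planes
perpendicular to the centerline tangent (0.5 mm in-plane sampling);
effective diameter is D = 2√(A/π), and segment diameters are measured
perpendicular to the centerline (the axial alternative was rejected as
it conflates tilt with dilation).  The flow waveform Q(t) is integrated
on the segment's mid-arclength plane and TF_peak is the frame of
maximum |Q| (earliest on ties).

The geometry is treated as quasi-static: one mesh, extracted from the
(single) lumen mask, is used for all timeframes.  Deformable-wall
tracking via registration is out of scope; for rigid phantoms this is
exact, for real data it ignores wall motion of a few millimetres over
the cycle.

## WSS estimator

Per node and timeframe, velocity is sampled by trilinear interpolation
at n points (default 3) equally spaced along the inward normal over a
cohort-specific length (AAA 12 mm, elderly 10 mm, young 9 mm — chosen
to span the different lumen sizes).  The wall itself enters as an exact
no-slip point, treated as an additional constraint rather than one of
the three samples.  A natural cubic spline per velocity component gives
the wall gradient dV/dn; its normal component is removed and the
tangential shear rate is scaled by the Carreau–Yasuda viscosity

    μ(γ̇) = μ∞ + (μ₀ − μ∞)[1 + (λγ̇)^a]^{(n−1)/a}

with μ∞ = 0.0035 Pa·s and literature-standard defaults μ₀ = 0.056 Pa·s,
λ = 3.313 s, a = 2, n = 0.3568 (all configurable; a Newtonian
constructor exists for validation).  Viscosity is evaluated once at the
estimated tangential shear rate; a fixed-point iteration changes
physiological results by well under 1% and was omitted.  The natural
cubic spline is deterministic and parameter-free; it reproduces linear
profiles exactly and systematically underestimates the wall gradient of
convex profiles, which is the dominant, resolution-dependent bias of
this estimator class.

Cycle integrals use a periodic trapezoid rule (exact weights for
non-uniform frame times).  RRT is reported as a configurable cap
(default 10³) with a per-node flag wherever (1 − 2·OSI)·TAWSS falls
below 10⁻³ Pa, preventing near-perfect-reversal nodes from dominating
segment means.  "Peak WSS" is the area-weighted mean |WSS| at the
segment's TF_peak.

### Validation regimes and what they show

* **Poiseuille** (R = 16 mm, 2.5 mm voxels): segment-mean WSS within
  20% of 4μQ/(πR³) — in practice ~9% low — with OSI < 0.01 and the RRT
  identity exact.  The error decreases strictly across 3.0 → 2.5 → 2.0
  mm voxels.
* **Womersley** (k = 0 + k = 1): validated with a glycerol-like test
  fluid (μ = 0.1 Pa·s, ρ = 1100 kg/m³, α ≈ 3.2), where the oscillatory
  boundary layer δ = √(2ν/ω) ≈ 5 mm spans several voxels.  There the
  estimated wall-shear waveform correlates with the Bessel solution at
  r ≈ 0.98 and OSI agrees within 0.02.  At blood viscosity and aortic
  α ≈ 13–17 the Stokes layer is ~1 mm — below voxel size — and the
  estimator necessarily returns an amplitude- and phase-smoothed
  waveform; no pointwise recovery claim is made in that regime.  This
  mirrors the known spatial-resolution dependence of image-based WSS:
  cohort comparisons remain meaningful because all subjects share the
  bias, but absolute WSS values are underestimates.

Passing these phantom tests shows the chain is internally correct under
its own assumptions (rigid wall, laminar axial flow, no partial-volume
or k-space effects).  It does not establish accuracy on real aortas,
where wall motion, in-plane velocity components, segmentation error and
partial-volume averaging add biases the phantom does not emulate.

## Cohort statistics

Segment summaries use area-weighted node means (node-count weighting is
available for sensitivity checks); missing-flagged nodes are excluded.
Abnormality thresholds are mean − 2 SD (floored at 0) for low WSS and
mean + 2 SD for high OSI/RRT, computed from the reference cohort either
at subject level (per-subject segment averages, the default) or pooled
node level — the two pooling levels give different thresholds and both
are supported because the appropriate level is a genuine design choice.
Exposure is the percentage of segment wall area *strictly* beyond the
threshold.  Thrombus-interface nodes (within one voxel diagonal of a
thrombus voxel) can be excluded from IAA means to compare whole-wall
and thrombus-free-wall values.

Two-group comparisons follow a Shapiro–Wilk gate at α = 0.05 per group:
a two-tailed unpaired t-test when both groups pass, a two-sided
Wilcoxon rank-sum otherwise (the gate applies per comparison; "either
group fails → rank-sum").  Significance is Bonferroni-corrected for the
two cohort contrasts only (α = 0.05/2 = 0.025), with no correction
across metrics or segments.  Identical constant groups are reported as
p = 1 with a degeneracy flag.

**Calibration design.**  The null experiment generates a pool of 80
subjects from one phantom spec (differing only in noise seed), analyzes
them identically, and compares disjoint random groups of 5 vs 5 for
each metric × segment — 200 comparisons.  Two pitfalls are deliberately
avoided: cohort labels must be identical across the two groups (the
cohort-specific inward length is an analysis difference that would turn
a null comparison into a systematic one), and diameter contrasts are
excluded because the phantom geometry is noise-free, making them
degenerate.  The observed significant-call rate (~0.02–0.03) lies
within the binomial 95% band around 0.025.

**Effect experiment.**  Aneurysm-like phantoms (fusiform bulge of
amplitude 0.8 in the IAA, flow rate halved) versus controls reproduce
the expected pattern: infrarenal peak WSS and TAWSS fall to ~0.23× the
control values, RRT rises ~5×, and the exposed low-WSS/high-RRT area
fractions are far larger in the bulged cohort.

## Problem sizes and runtime

The test suite and the acceptance script use deliberately small
phantoms — 100 mm vessels, 10–40 timeframes, 2.0–3.0 mm voxels, cohort
pools of 5–80 subjects — chosen so each experiment still satisfies its
resolution and sample-size preconditions (≥ 8 voxels across the
diameter, ≥ 3 subjects per group, ≥ 200 null comparisons, ≥ 10⁴ noise
samples) while the whole validation completes in minutes on one CPU.

## Known limitations

* Rigid, quasi-static geometry; no wall motion or registration.
* Single-wrap correction only; large coherently aliased regions are
  not recoverable by the local-median method.
* Voxel-center sampling without partial-volume or MR signal
  simulation; estimator biases on real data are larger than on
  phantoms.
* Absolute WSS at physiological Womersley numbers is systematically
  underestimated; comparisons between cohorts analyzed identically are
  the intended use.
* Carreau–Yasuda parameters other than μ∞ are literature defaults, not
  study-specific fits; with these defaults μ(γ̇) approaches μ∞ only
  like (λγ̇)^{n−1} (about 0.1% above μ∞ at γ̇ = 10⁶ s⁻¹).
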
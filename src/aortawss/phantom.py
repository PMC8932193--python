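"""Synthetic 4D-flow phantoms with analytic wall-shear ground truth.

Pulsatile laminar flow in a rigid straight cylinder (optionally with a
fusiform or saccular aneurysmal bulge) is generated from the exact
Womersley solution, parameterized by the flow-rate harmonics of the
waveform Q(t) = Re[sum_k Q_k exp(i k w t)] rather than by the pressure
gradient, since segment flow rate is the observable of interest.  The
k = 0 term produces the steady Poiseuille profile; each k >= 1 term is
the Bessel-function Womersley mode scaled so that its cross-sectional
flux equals Q_k exp(i k w t).

The generator rasterizes the analytic velocity onto a voxel grid (value
at voxel center, zero outside the lumen — a deliberate idealization
without partial-volume averaging), then applies, in order: additive
Gaussian velocity noise, a single phase wrap for components beyond
+/-VENC, and a smooth polynomial background-offset field, mirroring the
artifacts of a phase-contrast acquisition.  Analytic wall shear and the
derived TAWSS/OSI/RRT are exact on the straight part of the vessel and
are the oracle against which the surface WSS estimator is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, special

from aortawss.flow_io import (
    MaskVolume,
    VelocityField4D,
    n_polynomial_terms,
    order_for_n_terms,
    polynomial_design_for_grid,
)

#: density of whole blood, kg/m^3
BLOOD_DENSITY = 1060.0

#: arclength fractions at which the five synthetic landmarks are placed
LANDMARK_FRACTIONS = {
    "valve": 0.05,
    "brachiocephalic": 0.25,
    "left_subclavian": 0.35,
    "renal": 0.75,
    "iliac": 0.95,
}


@dataclass
class FlowWaveform:
    """Periodic flow-rate waveform given by its complex harmonics.

    ``harmonics`` is a list of ``(k, Q_k)`` with frequency index k >= 0
    and complex amplitude Q_k in m^3/s; the waveform is
    ``Q(t) = Re[sum_k Q_k exp(i k w t)]`` with ``w = 2 pi / period_s``.
    """

    period_s: float
    harmonics: list

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if len(self.harmonics) == 0:
            raise ValueError("at least one harmonic is required")
        clean = []
        for k, q in self.harmonics:
            k = int(k)
            if k < 0:
                raise ValueError("harmonic index must be >= 0")
            q = complex(q)
            if k == 0:
                if abs(q.imag) > 1e-15 * max(1.0, abs(q.real)):
                    raise ValueError("the k=0 (mean flow) amplitude must be real")
                q = complex(q.real, 0.0)
            clean.append((k, q))
        self.harmonics = clean

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period_s

    def flow_rate(self, t) -> np.ndarray:
        """Q(t) in m^3/s for scalar or array ``t`` (seconds)."""
        t = np.asarray(t, dtype=np.float64)
        q = np.zeros(t.shape, dtype=np.complex128)
        for k, qk in self.harmonics:
            q = q + qk * np.exp(1j * k * self.omega * t)
        return q.real


def default_waveform() -> FlowWaveform:
    """A physiological aortic-like waveform: 70 ml/s mean, strong first
    harmonic producing a short late-cycle flow reversal."""
    return FlowWaveform(period_s=1.0, harmonics=[(0, 7.0e-5), (1, 8.0e-5)])


@dataclass
class Bulge:
    """Gaussian aneurysmal dilation of the straight vessel.

    ``style='fusiform'`` dilates axisymmetrically; ``'saccular'``
    displaces the wall on one side only (the +x half).  ``amplitude``
    is the fractional radial increase at the bulge center.
    """

    center_mm: float
    amplitude: float
    width_mm: float
    style: str = "fusiform"

    def __post_init__(self) -> None:
        if self.style not in ("fusiform", "saccular"):
            raise ValueError("bulge style must be 'fusiform' or 'saccular'")
        if self.width_mm <= 0:
            raise ValueError("bulge width must be positive")
        if self.amplitude <= -1.0:
            raise ValueError("bulge amplitude would close the lumen")


@dataclass
class PhantomSpec:
    """Full description of one synthetic 4D-flow acquisition.

    Defaults mirror a whole-aorta protocol: 2.5 mm isotropic voxels, 40
    timeframes per cycle, VENC 150 cm/s (within the 100-200 cm/s range
    used clinically), and a lumen wide enough for at least 8 voxels
    across the diameter.
    """

    radius_mm: float = 10.0
    length_mm: float = 100.0
    bulge: Optional[Bulge] = None
    waveform: FlowWaveform = field(default_factory=default_waveform)
    mu_Pa_s: float = 0.0035
    rho_kg_m3: float = BLOOD_DENSITY
    spacing_mm: float = 2.5
    n_timeframes: int = 40
    venc_cm_s: float = 150.0
    noise_sd_cm_s: float = 5.0
    wrap_injection: bool = False
    offset_coeffs: Optional[np.ndarray] = None
    with_thrombus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.radius_mm, self.length_mm, self.spacing_mm) <= 0:
            raise ValueError("radius, length and spacing must be positive")
        if self.mu_Pa_s <= 0 or self.rho_kg_m3 <= 0:
            raise ValueError("viscosity and density must be positive")
        if self.n_timeframes < 2:
            raise ValueError("at least 2 timeframes required")
        if self.noise_sd_cm_s < 0:
            raise ValueError("noise SD must be non-negative")
        if 2.0 * self.radius_mm / self.spacing_mm < 8.0:
            raise ValueError(
                "fewer than 8 voxels across the lumen diameter; increase "
                "radius_mm or decrease spacing_mm"
            )
        if self.offset_coeffs is not None:
            arr = np.asarray(self.offset_coeffs, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("offset_coeffs must have shape (n_terms, 3)")
            order_for_n_terms(arr.shape[0])  # raises if not a full basis
            self.offset_coeffs = arr


@dataclass
class AnalyticTruth:
    """Exact wall-shear time series and indices for the straight vessel."""

    times_s: np.ndarray
    wall_shear_Pa: np.ndarray  # signed axial wall shear at each time
    tawss_Pa: float
    osi: float
    rrt: float
    rrt_capped: bool
    womersley_alpha: dict  # harmonic index -> alpha


@dataclass
class PhantomDataset:
    """Everything :func:`build_phantom` produces for one synthetic subject."""

    field: VelocityField4D
    lumen: MaskVolume
    static_tissue: MaskVolume
    thrombus: Optional[MaskVolume]
    truth: AnalyticTruth
    landmarks: dict
    spec: PhantomSpec
    clean_velocity: np.ndarray  # pre-corruption velocity, cm/s
    straight_z_mm: tuple  # (lo, hi) axial range where the truth applies


# ---------------------------------------------------------------------------
# analytic Womersley solution


def _lambda(alpha: float) -> complex:
    # i^(3/2) alpha, the Womersley Bessel argument
    return alpha * np.exp(3j * np.pi / 4.0)


def womersley_alpha(waveform: FlowWaveform, radius_mm: float, mu_Pa_s: float,
                    rho_kg_m3: float) -> dict:
    """Womersley number alpha = R sqrt(k w / nu) for each harmonic k >= 1."""
    R = radius_mm * 1e-3
    nu = mu_Pa_s / rho_kg_m3
    return {
        k: float(R * np.sqrt(k * waveform.omega / nu))
        for k, _ in waveform.harmonics
        if k >= 1
    }


def _harmonic_profile_factors(waveform, radius_mm, mu_Pa_s, rho_kg_m3):
    """Per-harmonic data for velocity and wall-shear evaluation.

    For each (k, Q_k) returns (k, Q_k, Lambda_k, flux_factor) where the
    k >= 1 velocity mode is
    ``u_k(r) = Q_k / (pi R^2) * (1 - J0(L r/R)/J0(L)) / flux_factor``
    with ``flux_factor = 1 - 2 J1(L) / (L J0(L))``, which makes the
    cross-sectional flux of the mode exactly Q_k.
    """
    alphas = womersley_alpha(waveform, radius_mm, mu_Pa_s, rho_kg_m3)
    out = []
    for k, qk in waveform.harmonics:
        if k == 0:
            out.append((k, qk, None, None))
            continue
        lam = _lambda(alphas[k])
        j0 = special.jv(0, lam)
        j1 = special.jv(1, lam)
        flux_factor = 1.0 - 2.0 * j1 / (lam * j0)
        if not (np.isfinite(j0) and np.isfinite(j1) and np.isfinite(flux_factor)):
            raise ValueError(
                f"Bessel evaluation not finite at alpha={alphas[k]:.3g}; "
                "check radius, period, viscosity and density"
            )
        out.append((k, qk, lam, flux_factor))
    return out


def womersley_velocity_profile(r_frac, t, waveform: FlowWaveform,
                               radius_mm: float, mu_Pa_s: float,
                               rho_kg_m3: float = BLOOD_DENSITY) -> np.ndarray:
    """Axial velocity (m/s) at relative radius ``r_frac`` and time ``t``.

    Superposition of the steady Poiseuille profile for the k = 0
    harmonic and the Womersley (Bessel) solution for each k >= 1, each
    mode carrying exactly its prescribed flux, so the cross-sectional
    flux at time t equals Q(t).  ``r_frac`` and ``t`` broadcast.
    """
    r_frac = np.asarray(r_frac, dtype=np.float64)
    if np.any(r_frac < 0) or np.any(r_frac > 1):
        raise ValueError("r_frac must lie in [0, 1]")
    t = np.asarray(t, dtype=np.float64)
    R = radius_mm * 1e-3
    area = np.pi * R * R
    omega = waveform.omega
    u = np.zeros(np.broadcast_shapes(r_frac.shape, t.shape), dtype=np.float64)
    for k, qk, lam, flux_factor in _harmonic_profile_factors(
        waveform, radius_mm, mu_Pa_s, rho_kg_m3
    ):
        if k == 0:
            u = u + (2.0 * qk.real / area) * (1.0 - r_frac**2)
        else:
            shape = (qk / area) * (1.0 - special.jv(0, lam * r_frac)
                                   / special.jv(0, lam)) / flux_factor
            u = u + (shape * np.exp(1j * k * omega * t)).real
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite Womersley velocity; check parameters")
    return u


def analytic_wall_shear(waveform: FlowWaveform, radius_mm: float,
                        mu_Pa_s: float, rho_kg_m3: float, t) -> np.ndarray:
    """Signed axial wall shear stress tau_w(t) in Pa (positive = forward).

    ``tau_w = -mu du/dr`` at r = R; the Poiseuille term contributes
    ``4 mu Q_0 / (pi R^3)`` and each Womersley mode its exact complex
    wall gradient.
    """
    t = np.asarray(t, dtype=np.float64)
    R = radius_mm * 1e-3
    area = np.pi * R * R
    omega = waveform.omega
    tau = np.zeros(t.shape, dtype=np.float64)
    for k, qk, lam, flux_factor in _harmonic_profile_factors(
        waveform, radius_mm, mu_Pa_s, rho_kg_m3
    ):
        if k == 0:
            tau = tau + 4.0 * mu_Pa_s * qk.real / (np.pi * R**3)
        else:
            # d/dr [1 - J0(lam r/R)/J0(lam)] at r=R is (lam/R) J1(lam)/J0(lam)
            dudr = (qk / area) * (lam / R) * special.jv(1, lam) \
                / special.jv(0, lam) / flux_factor
            tau = tau + (-mu_Pa_s * dudr * np.exp(1j * k * omega * t)).real
    return tau


def shear_indices_from_series(tau: np.ndarray, rrt_cap: float = 1e3,
                              denom_floor: float = 1e-3):
    """TAWSS, OSI and RRT from a uniformly sampled signed shear series.

    Uniform samples over one period make the periodic trapezoid rule a
    plain mean.  OSI uses the magnitude of the signed time integral in
    the numerator; RRT = 1/((1 - 2 OSI) * TAWSS), reported as
    ``rrt_cap`` with a flag when the denominator falls below
    ``denom_floor``.
    """
    tau = np.asarray(tau, dtype=np.float64)
    tawss = float(np.mean(np.abs(tau)))
    if tawss == 0.0:
        return 0.0, 0.0, rrt_cap, True
    osi = 0.5 * (1.0 - abs(float(np.mean(tau))) / tawss)
    osi = float(min(max(osi, 0.0), 0.5))
    denom = (1.0 - 2.0 * osi) * tawss
    if denom < denom_floor:
        return tawss, osi, float(rrt_cap), True
    return tawss, osi, float(1.0 / denom), False


def analytic_wall_metrics(waveform: FlowWaveform, radius_mm: float,
                          mu_Pa_s: float, rho_kg_m3: float = BLOOD_DENSITY,
                          n_samples: int = 256, rrt_cap: float = 1e3,
                          denom_floor: float = 1e-3) -> AnalyticTruth:
    """Exact TAWSS/OSI/RRT of the straight vessel by periodic quadrature.

    The signed wall shear is treated as a 1-D vector along the axis, so
    the OSI numerator is the magnitude of the signed integral.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    times = np.linspace(0.0, waveform.period_s, n_samples, endpoint=False)
    tau = analytic_wall_shear(waveform, radius_mm, mu_Pa_s, rho_kg_m3, times)
    tawss, osi, rrt, capped = shear_indices_from_series(
        tau, rrt_cap=rrt_cap, denom_floor=denom_floor
    )
    return AnalyticTruth(
        times_s=times,
        wall_shear_Pa=tau,
        tawss_Pa=tawss,
        osi=osi,
        rrt=rrt,
        rrt_capped=capped,
        womersley_alpha=womersley_alpha(waveform, radius_mm, mu_Pa_s, rho_kg_m3),
    )


# ---------------------------------------------------------------------------
# rasterization


def _boundary_radius(spec: PhantomSpec, z_mm: np.ndarray,
                     cos_theta: np.ndarray) -> np.ndarray:
    """Local lumen boundary radius R_b(z, theta) in mm."""
    R = spec.radius_mm
    if spec.bulge is None:
        return np.full(np.broadcast_shapes(z_mm.shape, cos_theta.shape), R)
    b = spec.bulge
    g = np.exp(-((z_mm - b.center_mm) ** 2) / (2.0 * b.width_mm**2))
    if b.style == "fusiform":
        bump = b.amplitude * g
    else:  # saccular: one-sided, smooth across the seam
        bump = b.amplitude * g * np.clip(cos_theta, 0.0, None) ** 2
    return R * (1.0 + np.broadcast_to(bump, np.broadcast_shapes(z_mm.shape, cos_theta.shape)))


def build_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Rasterize the analytic flow onto a voxel grid and corrupt it.

    The vessel axis is the world z axis; the grid is RAS with isotropic
    spacing, the axis passing through in-plane voxel centers.  Voxel
    velocity equals the analytic velocity at the voxel center (zero
    outside the lumen).  Corruption is applied in the order noise ->
    phase wrap -> background offset; a cylindrical static-tissue shell
    disjoint from the lumen surrounds the vessel.  Identical spec and
    seed give bit-identical output.
    """
    s = spec.spacing_mm
    R = spec.radius_mm
    amp = spec.bulge.amplitude if spec.bulge is not None else 0.0
    r_max = R * (1.0 + max(amp, 0.0))
    shell_gap, shell_thick = 1.5 * s, 3.0 * s
    half = r_max + shell_gap + shell_thick + 1.5 * s
    n_half = int(np.ceil(half / s))
    nx = ny = 2 * n_half + 1
    nz = int(round(spec.length_mm / s))
    affine = np.diag([s, s, s, 1.0])
    affine[0, 3] = -n_half * s
    affine[1, 3] = -n_half * s
    affine[2, 3] = 0.5 * s  # z covers (0, length_mm)

    x = (np.arange(nx) - n_half) * s
    y = (np.arange(ny) - n_half) * s
    z = np.arange(nz) * s + 0.5 * s
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    dist = np.hypot(X, Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(dist > 0, X / np.maximum(dist, 1e-12), 1.0)
    rb = _boundary_radius(spec, Z, cos_theta)
    if np.any(rb <= 0):
        raise ValueError("bulge parameters close the lumen")
    lumen = dist <= rb

    # every axial slice must be one connected region (simply connected lumen)
    for k in range(nz):
        _, n_comp = ndimage.label(lumen[:, :, k])
        if n_comp != 1:
            raise ValueError("lumen cross-section is not a single connected region")

    # flux-conserving local scaling: for a profile u(r/Rb) on a section with
    # boundary Rb(theta), flux scales with mean_theta(Rb^2)/R^2
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    z_line = z[None, :]
    rb_theta = _boundary_radius(spec, z_line, np.cos(theta)[:, None])
    mean_rb2 = (rb_theta**2).mean(axis=0)  # per z-slice
    scale_z = (R**2) / mean_rb2

    times = np.arange(spec.n_timeframes) * spec.waveform.period_s \
        / spec.n_timeframes
    r_frac = np.where(lumen, np.minimum(dist / rb, 1.0), 0.0)
    clean = np.zeros((nx, ny, nz, spec.n_timeframes, 3))
    lum_idx = np.nonzero(lumen)
    rf = r_frac[lum_idx]
    sc = scale_z[lum_idx[2]]
    for j, t in enumerate(times):
        u = womersley_velocity_profile(
            rf, t, spec.waveform, spec.radius_mm, spec.mu_Pa_s, spec.rho_kg_m3
        )
        clean[lum_idx[0], lum_idx[1], lum_idx[2], j, 2] = 100.0 * sc * u  # cm/s

    static = (dist >= r_max + shell_gap) & (dist <= r_max + shell_gap + shell_thick)
    static &= ~lumen

    rng = np.random.default_rng(spec.seed)
    corrupted = clean.copy()
    if spec.noise_sd_cm_s > 0:
        tissue = lumen | static
        noise = rng.normal(
            0.0, spec.noise_sd_cm_s,
            size=(int(tissue.sum()), spec.n_timeframes, 3),
        )
        corrupted[tissue] += noise
    if spec.wrap_injection:
        venc = spec.venc_cm_s
        if np.any(np.abs(corrupted) >= 3.0 * venc):
            raise ValueError("velocities beyond the single-wrap range (3*VENC)")
        over = np.abs(corrupted) > venc
        corrupted = np.where(
            over, corrupted - np.sign(corrupted) * 2.0 * venc, corrupted
        )
    if spec.offset_coeffs is not None:
        order = order_for_n_terms(spec.offset_coeffs.shape[0])
        design = polynomial_design_for_grid((nx, ny, nz), affine, order)
        offset = (design @ spec.offset_coeffs).reshape(nx, ny, nz, 1, 3)
        corrupted = corrupted + offset

    thrombus_mask = None
    if spec.with_thrombus:
        if spec.bulge is None:
            raise ValueError("a thrombus requires a bulge")
        b = spec.bulge
        near_wall = lumen & (dist >= rb - 1.5 * s)
        thrombus = near_wall & (np.abs(Z - b.center_mm) <= b.width_mm)
        thrombus_mask = MaskVolume(data=thrombus, affine=affine, role="thrombus")

    truth = analytic_wall_metrics(
        spec.waveform, spec.radius_mm, spec.mu_Pa_s, spec.rho_kg_m3,
        n_samples=max(256, 4 * spec.n_timeframes),
    )
    # resample the signed wall shear at the acquisition timeframes as well
    truth = AnalyticTruth(
        times_s=times,
        wall_shear_Pa=analytic_wall_shear(
            spec.waveform, spec.radius_mm, spec.mu_Pa_s, spec.rho_kg_m3, times
        ),
        tawss_Pa=truth.tawss_Pa,
        osi=truth.osi,
        rrt=truth.rrt,
        rrt_capped=truth.rrt_capped,
        womersley_alpha=truth.womersley_alpha,
    )

    landmarks = {
        name: np.array([0.0, 0.0, frac * spec.length_mm])
        for name, frac in LANDMARK_FRACTIONS.items()
    }
    if spec.bulge is not None:
        lo = spec.bulge.center_mm - 2.0 * spec.bulge.width_mm
        hi = spec.bulge.center_mm + 2.0 * spec.bulge.width_mm
        straight = (0.0, lo) if lo > spec.length_mm - hi else (hi, spec.length_mm)
    else:
        straight = (0.0, spec.length_mm)

    fld = VelocityField4D(
        velocity=corrupted,
        affine=affine,
        period_s=spec.waveform.period_s,
        venc_cm_s=spec.venc_cm_s,
        timeframe_times_s=times,
    )
    return PhantomDataset(
        field=fld,
        lumen=MaskVolume(data=lumen, affine=affine, role="lumen"),
        static_tissue=MaskVolume(data=static, affine=affine, role="static_tissue"),
        thrombus=thrombus_mask,
        truth=truth,
        landmarks=landmarks,
        spec=spec,
        clean_velocity=clean,
        straight_z_mm=straight,
    )
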
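"""Wall shear stress vectors on the lumen surface and derived maps.

For every surface node and timeframe the velocity is sampled by
trilinear interpolation at a few points along the inward wall normal, a
natural cubic spline per velocity component is fit through the no-slip
wall point and the samples, and its derivative at the wall gives the
wall-normal velocity gradient dV/dn.  The normal component of the
gradient is removed, leaving the tangential shear-rate vector, and

    WSS = mu(|gamma_t|) * gamma_t        [Pa]

with the dynamic viscosity mu from the Carreau-Yasuda shear-thinning
model (infinite-shear viscosity 0.0035 Pa s for blood).  The inward
sampling length is cohort-specific (12 / 10 / 9 mm for AAA patients,
elderly and young controls) to account for lumen-size differences.

Cycle-averaged maps follow:

    TAWSS = (1/T) int_0^T |WSS| dt
    OSI   = 0.5 (1 - |int_0^T WSS dt| / int_0^T |WSS| dt)
    RRT   = 1 / ((1 - 2 OSI) * TAWSS)

integrated with a periodic trapezoid rule; RRT is reported as a cap
with a flag where the denominator underflows (OSI -> 0.5 or TAWSS -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

from aortawss.flow_io import VelocityField4D, world_to_voxel
from aortawss.geometry import SurfaceMesh


@dataclass
class ViscosityModel:
    """Carreau-Yasuda shear-thinning viscosity.

    mu(g) = mu_inf + (mu_zero - mu_inf) * [1 + (lambda g)^a]^((n-1)/a)

    Defaults are the literature-standard blood parameters; only the
    infinite-shear viscosity 0.0035 Pa s is pinned by convention, the
    rest are configurable.
    """

    mu_inf_Pa_s: float = 0.0035
    mu_zero_Pa_s: float = 0.056
    lambda_s: float = 3.313
    a_exponent: float = 2.0
    n_index: float = 0.3568

    def __post_init__(self) -> None:
        if not (self.mu_zero_Pa_s >= self.mu_inf_Pa_s > 0):
            raise ValueError("require mu_zero >= mu_inf > 0")
        if self.lambda_s <= 0 or self.a_exponent <= 0:
            raise ValueError("lambda_s and a_exponent must be positive")
        if not (0 < self.n_index <= 1):
            raise ValueError("power-law index must lie in (0, 1]")

    @classmethod
    def newtonian(cls, mu_Pa_s: float) -> "ViscosityModel":
        """Constant-viscosity model (mu_zero = mu_inf)."""
        return cls(mu_inf_Pa_s=mu_Pa_s, mu_zero_Pa_s=mu_Pa_s)


@dataclass
class WSSConfig:
    """Estimator settings: inward profile sampling and RRT capping."""

    n_profile_points: int = 3
    inward_length_mm: dict = field(
        default_factory=lambda: {"AAA": 12.0, "elderly": 10.0, "young": 9.0}
    )
    rrt_cap: float = 1e3
    denom_floor: float = 1e-3  # Pa; RRT capped below this (1 - 2 OSI) * TAWSS

    def __post_init__(self) -> None:
        if self.n_profile_points < 2:
            raise ValueError("need at least 2 profile points")
        if any(v <= 0 for v in self.inward_length_mm.values()):
            raise ValueError("inward lengths must be positive")


@dataclass
class WSSVectorField:
    """Per-node, per-timeframe tangential wall shear stress vectors."""

    values_Pa: np.ndarray        # (N, nt, 3); NaN where missing
    missing: np.ndarray          # (N,) bool: any sample fell outside the grid
    timeframe_times_s: np.ndarray
    period_s: float

    @property
    def n_nodes(self) -> int:
        return self.values_Pa.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.values_Pa, axis=-1)


@dataclass
class HemodynamicMaps:
    """Per-node TAWSS (Pa), OSI and RRT with cap/missing flags."""

    tawss_Pa: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    rrt_capped: np.ndarray
    missing: np.ndarray


def carreau_yasuda(shear_rate_s, model: Optional[ViscosityModel] = None) -> np.ndarray:
    """Dynamic viscosity (Pa s) at shear rate ``shear_rate_s`` (1/s)."""
    if model is None:
        model = ViscosityModel()
    g = np.asarray(shear_rate_s, dtype=np.float64)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    lam_g = (model.lambda_s * g) ** model.a_exponent
    mu = model.mu_inf_Pa_s + (model.mu_zero_Pa_s - model.mu_inf_Pa_s) * (
        1.0 + lam_g
    ) ** ((model.n_index - 1.0) / model.a_exponent)
    return mu if mu.shape else float(mu)


def compute_wss_field(
    fld: VelocityField4D,
    mesh: SurfaceMesh,
    config: Optional[WSSConfig] = None,
    model: Optional[ViscosityModel] = None,
    cohort: str = "elderly",
) -> WSSVectorField:
    """Estimate the WSS vector at every surface node and timeframe.

    Velocity is sampled at ``n_profile_points`` equally spaced points
    along the inward normal over the cohort's inward length (the wall
    itself enters the spline as an exact no-slip point).  Nodes with
    any sample outside the velocity grid are flagged missing (NaN).
    """
    config = config or WSSConfig()
    model = model or ViscosityModel()
    if cohort not in config.inward_length_mm:
        raise ValueError(f"no inward length configured for cohort '{cohort}'")
    L = config.inward_length_mm[cohort]
    n_pts = config.n_profile_points
    dists = L * np.arange(1, n_pts + 1) / n_pts  # mm from the wall

    n_nodes = mesh.n_nodes
    nt = fld.n_timeframes
    shape = np.array(fld.shape)

    # sample coordinates: (n_pts, n_nodes, 3) voxel indices
    pts = mesh.nodes[None, :, :] - dists[:, None, None] * mesh.outward_normals[None, :, :]
    ijk = world_to_voxel(fld.affine, pts.reshape(-1, 3)).reshape(n_pts, n_nodes, 3)
    outside = np.any((ijk < 0) | (ijk > shape - 1), axis=(0, 2))

    samples = np.empty((n_pts, n_nodes, nt, 3))
    coords = ijk.reshape(-1, 3).T  # (3, n_pts*n_nodes)
    for j in range(nt):
        for c in range(3):
            samples[..., j, c] = map_coordinates(
                fld.velocity[..., j, c], coords, order=1,
                mode="constant", cval=0.0,
            ).reshape(n_pts, n_nodes)

    # natural cubic spline through the wall (no-slip) and the samples;
    # derivative at the wall in (cm/s)/mm -> *10 for 1/s
    x = np.concatenate([[0.0], dists])
    y = np.concatenate([np.zeros((1, n_nodes, nt, 3)), samples], axis=0)
    spline = CubicSpline(x, y, axis=0, bc_type="natural")
    dv_dn = spline(0.0, 1) * 10.0  # (n_nodes, nt, 3), 1/s

    normals = mesh.outward_normals[:, None, :]
    gamma_t = dv_dn - np.sum(dv_dn * normals, axis=-1, keepdims=True) * normals
    mu = carreau_yasuda(np.linalg.norm(gamma_t, axis=-1), model)
    wss = np.asarray(mu)[..., None] * gamma_t
    wss[outside] = np.nan
    return WSSVectorField(
        values_Pa=wss,
        missing=outside,
        timeframe_times_s=fld.timeframe_times_s,
        period_s=fld.period_s,
    )


def periodic_trapezoid_weights(times: np.ndarray, period: float) -> np.ndarray:
    """Quadrature weights for a periodic signal sampled at ``times``.

    ``w_j = (t_{j+1} - t_{j-1}) / 2`` with indices wrapped modulo the
    period; for uniform sampling this reduces to ``period / n``.
    """
    t = np.asarray(times, dtype=np.float64)
    fwd = np.mod(np.roll(t, -1) - t, period)
    bwd = np.mod(t - np.roll(t, 1), period)
    return 0.5 * (fwd + bwd)


def compute_hemodynamic_maps(
    wss: WSSVectorField,
    times: Optional[np.ndarray] = None,
    period_s: Optional[float] = None,
    config: Optional[WSSConfig] = None,
) -> HemodynamicMaps:
    """TAWSS, OSI and RRT per node by periodic trapezoid quadrature."""
    config = config or WSSConfig()
    times = wss.timeframe_times_s if times is None else np.asarray(times)
    period = wss.period_s if period_s is None else float(period_s)
    w = periodic_trapezoid_weights(times, period)

    vals = wss.values_Pa
    mag = np.linalg.norm(vals, axis=-1)          # (N, nt)
    int_mag = mag @ w                            # (N,)
    int_vec = np.einsum("ntc,t->nc", vals, w)    # (N, 3)
    tawss = int_mag / period
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.linalg.norm(int_vec, axis=-1) / int_mag
    osi = np.where(int_mag > 0, 0.5 * (1.0 - ratio), 0.0)
    osi = np.clip(osi, 0.0, 0.5)
    denom = (1.0 - 2.0 * osi) * tawss
    capped = denom < config.denom_floor
    with np.errstate(divide="ignore"):
        rrt = np.where(capped, config.rrt_cap, 1.0 / np.where(capped, 1.0, denom))
    missing = wss.missing | ~np.isfinite(tawss)
    tawss = np.where(wss.missing, np.nan, tawss)
    osi = np.where(wss.missing, np.nan, osi)
    rrt = np.where(wss.missing, np.nan, rrt)
    return HemodynamicMaps(
        tawss_Pa=tawss, osi=osi, rrt=rrt,
        rrt_capped=capped & ~missing, missing=missing,
    )


def write_maps_csv(path, mesh: SurfaceMesh, maps: HemodynamicMaps) -> None:
    """Per-node map export: node_id, coordinates, indices and flags."""
    import pandas as pd

    pd.DataFrame(
        {
            "node_id": np.arange(mesh.n_nodes),
            "x_mm": mesh.nodes[:, 0],
            "y_mm": mesh.nodes[:, 1],
            "z_mm": mesh.nodes[:, 2],
            "tawss_Pa": maps.tawss_Pa,
            "osi": maps.osi,
            "rrt": maps.rrt,
            "rrt_capped": maps.rrt_capped.astype(int),
            "missing": maps.missing.astype(int),
        }
    ).to_csv(path, index=False)
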
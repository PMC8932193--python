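"""Containers and offline preprocessing for 4D flow MRI velocity data.

Velocity is stored in cm/s (the VENC convention) on a regular voxel grid
with a RAS voxel-to-world affine in mm; timeframes sample one cardiac
cycle of length ``period_s``.  Besides NIfTI I/O, the module implements
the two offline corrections applied to phase-contrast velocity data
before hemodynamic analysis:

* single phase-wrap correction against a local spatio-temporal median
  (velocities beyond +/-VENC alias by 2*VENC);
* background phase-offset removal by a weighted polynomial fit (default
  order 4) to static tissue, weights proportional to the inverse
  temporal variance so that pulsatile contamination is down-weighted;
* peak-systole detection as the timeframe with maximum mean velocity
  magnitude over the lumen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: grid geometry agreement tolerance for paired volumes (mm)
GRID_TOL_MM = 1e-4

MASK_ROLES = ("lumen", "static_tissue", "thrombus")


# ---------------------------------------------------------------------------
# containers


@dataclass
class VelocityField4D:
    """Three-directional velocity over a cardiac cycle on a voxel grid.

    Parameters
    ----------
    velocity:
        Array of shape ``(nx, ny, nz, nt, 3)`` in cm/s; the last axis
        holds the x, y, z world components.
    affine:
        4x4 voxel-to-world (mm) transform, RAS orientation.
    period_s:
        Cardiac period T in seconds.
    venc_cm_s:
        Velocity-encoding limit in cm/s.
    timeframe_times_s:
        Frame midpoints in ``[0, T)``, strictly increasing.
    """

    velocity: np.ndarray
    affine: np.ndarray
    period_s: float
    venc_cm_s: float
    timeframe_times_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.timeframe_times_s = np.asarray(self.timeframe_times_s, dtype=np.float64)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValueError("velocity must have shape (nx, ny, nz, nt, 3)")
        nt = self.velocity.shape[3]
        if nt < 2:
            raise ValueError("at least 2 timeframes required")
        if self.timeframe_times_s.shape != (nt,):
            raise ValueError("timeframe_times_s length must match timeframe count")
        if np.any(np.diff(self.timeframe_times_s) <= 0):
            raise ValueError("timeframe times must be strictly increasing")
        if self.timeframe_times_s[0] < 0 or self.timeframe_times_s[-1] >= self.period_s:
            raise ValueError("timeframe times must lie in [0, period_s)")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[:3]

    @property
    def n_timeframes(self) -> int:
        return self.velocity.shape[3]

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def speed(self) -> np.ndarray:
        """Velocity magnitude, shape ``(nx, ny, nz, nt)`` in cm/s."""
        return np.linalg.norm(self.velocity, axis=-1)


@dataclass
class MaskVolume:
    """Binary voxel mask on the same grid as a :class:`VelocityField4D`."""

    data: np.ndarray
    affine: np.ndarray
    role: str = "lumen"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"mask '{self.role}' is not binary")
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role '{self.role}'")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))


def grids_match(affine_a, affine_b, shape_a, shape_b, tol_mm: float = GRID_TOL_MM) -> bool:
    return tuple(shape_a) == tuple(shape_b) and bool(
        np.all(np.abs(np.asarray(affine_a) - np.asarray(affine_b)) <= tol_mm)
    )


# ---------------------------------------------------------------------------
# coordinate helpers


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices ``(N, 3)`` to world mm coordinates."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world mm coordinates ``(N, 3)`` to (fractional) voxel indices."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def grid_world_coordinates(shape, affine) -> np.ndarray:
    """World mm coordinates of all voxel centers, shape ``(*shape, 3)``."""
    idx = np.indices(shape, dtype=np.float64)
    ijk = np.stack([idx[0], idx[1], idx[2]], axis=-1).reshape(-1, 3)
    return voxel_to_world(affine, ijk).reshape(*shape, 3)


# ---------------------------------------------------------------------------
# polynomial basis for background offsets (shared with the phantom)


def polynomial_exponents(order: int) -> list[tuple[int, int, int]]:
    """Monomial exponents of total degree <= order, in deterministic order."""
    exps = []
    for total in range(order + 1):
        for i in range(total, -1, -1):
            for j in range(total - i, -1, -1):
                exps.append((i, j, total - i - j))
    return exps


def n_polynomial_terms(order: int) -> int:
    return math.comb(order + 3, 3)


def _scaled_coordinates(shape, affine) -> np.ndarray:
    """Voxel-center world coordinates scaled to the grid bounding box.

    Centering and scaling to [-1, 1] per axis conditions the polynomial
    design matrix; the mapping is a pure function of grid geometry so
    the same basis is reproducible at injection and at fit time.
    """
    coords = grid_world_coordinates(shape, affine).reshape(-1, 3)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    center = (lo + hi) / 2.0
    half = np.maximum((hi - lo) / 2.0, 1.0)
    return (coords - center) / half


def polynomial_design(scaled: np.ndarray, order: int) -> np.ndarray:
    """Design matrix ``(N, n_terms)`` of monomials on scaled coordinates."""
    exps = polynomial_exponents(order)
    cols = [
        scaled[:, 0] ** i * scaled[:, 1] ** j * scaled[:, 2] ** k
        for (i, j, k) in exps
    ]
    return np.stack(cols, axis=1)


def polynomial_design_for_grid(shape, affine, order: int) -> np.ndarray:
    return polynomial_design(_scaled_coordinates(shape, affine), order)


def order_for_n_terms(n_terms: int) -> int:
    for order in range(0, 16):
        if n_polynomial_terms(order) == n_terms:
            return order
    raise ValueError(f"{n_terms} is not a full polynomial term count")


# ---------------------------------------------------------------------------
# NIfTI dataset I/O


_COMPONENTS = ("x", "y", "z")


def write_velocity_dataset(path, fld: VelocityField4D, masks=()) -> None:
    """Write a velocity dataset as per-component 4-D NIfTI files.

    ``velocity_{x,y,z}.nii`` hold one scalar volume per component with
    dimension order (x, y, z, t) in cm/s; masks are written as uint8
    ``mask_{role}.nii``; scan metadata goes to a JSON sidecar.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for c, name in enumerate(_COMPONENTS):
        img = nib.Nifti1Image(fld.velocity[..., c], fld.affine)
        nib.save(img, path / f"velocity_{name}.nii")
    for mask in masks:
        if not grids_match(mask.affine, fld.affine, mask.data.shape, fld.shape):
            raise ValueError(f"mask '{mask.role}' grid does not match velocity grid")
        img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
        nib.save(img, path / f"mask_{mask.role}.nii")
    meta = {
        "period_s": fld.period_s,
        "venc_cm_s": fld.venc_cm_s,
        "timeframe_times_s": fld.timeframe_times_s.tolist(),
        **fld.metadata,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_velocity_dataset(path) -> tuple[VelocityField4D, dict]:
    """Load a dataset written by :func:`write_velocity_dataset`.

    Returns the velocity field and a dict of masks keyed by role.  All
    volumes must share shape and affine within ``GRID_TOL_MM``.
    """
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    comps = []
    affine = None
    for name in _COMPONENTS:
        f = path / f"velocity_{name}.nii"
        if not f.exists():
            raise FileNotFoundError(f"missing velocity component file {f.name}")
        img = nib.load(str(f))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if affine is None:
            affine = img.affine
        elif not grids_match(img.affine, affine, arr.shape, comps[0].shape):
            raise ValueError(f"component '{name}' grid mismatch")
        comps.append(arr)
    velocity = np.stack(comps, axis=-1)
    fld = VelocityField4D(
        velocity=velocity,
        affine=affine,
        period_s=meta["period_s"],
        venc_cm_s=meta["venc_cm_s"],
        timeframe_times_s=np.asarray(meta["timeframe_times_s"]),
        metadata={
            k: v
            for k, v in meta.items()
            if k not in ("period_s", "venc_cm_s", "timeframe_times_s")
        },
    )
    masks = {}
    for role in MASK_ROLES:
        f = path / f"mask_{role}.nii"
        if f.exists():
            img = nib.load(str(f))
            data = np.asarray(img.dataobj)
            if not grids_match(img.affine, affine, data.shape, fld.shape):
                raise ValueError(f"mask '{role}' grid does not match velocity grid")
            masks[role] = MaskVolume(data=data, affine=img.affine, role=role)
    if "lumen" in masks and "static_tissue" in masks:
        if np.any(masks["lumen"].data & masks["static_tissue"].data):
            raise ValueError("lumen and static_tissue masks overlap")
    return fld, masks


# ---------------------------------------------------------------------------
# preprocessing


def unwrap_phase(fld: VelocityField4D) -> tuple[VelocityField4D, int]:
    """Correct single phase wraps against a local spatio-temporal median.

    Each component is compared to the median of its 3x3x3x3 neighborhood
    (center excluded, periodic in time).  Voxels disagreeing by more
    than VENC are shifted by the +/-2*VENC that minimizes the residual
    disagreement.  Voxels whose residual still exceeds VENC after one
    shift are left unchanged and counted.  Idempotent on wrap-free data.

    Returns the corrected field and the number of flagged voxels.
    """
    if fld.venc_cm_s <= 0:
        raise ValueError("venc_cm_s must be positive")
    venc = fld.venc_cm_s
    footprint = np.ones((3, 3, 3, 3), dtype=bool)
    footprint[1, 1, 1, 1] = False
    out = fld.velocity.copy()
    n_flagged = 0
    for c in range(3):
        comp = fld.velocity[..., c]
        # periodic in time: pad the frame axis by one cycle-wrapped frame
        padded = np.concatenate([comp[..., -1:], comp, comp[..., :1]], axis=3)
        med = ndimage.median_filter(padded, footprint=footprint, mode="nearest")
        med = med[..., 1:-1]
        delta = comp - med
        suspect = np.abs(delta) > venc
        candidate = comp - 2.0 * venc * np.sign(delta)
        resolved = suspect & (np.abs(candidate - med) <= venc)
        comp_out = comp.copy()
        comp_out[resolved] = candidate[resolved]
        n_flagged += int(np.count_nonzero(suspect & ~resolved))
        out[..., c] = comp_out
    return replace(fld, velocity=out), n_flagged


def correct_background_offset(
    fld: VelocityField4D,
    static: MaskVolume,
    order: int = 4,
    variance_floor: float = 1e-3,
) -> tuple[VelocityField4D, np.ndarray]:
    """Remove background phase offsets by a weighted polynomial fit.

    Per component, a 3-D polynomial of total degree ``order`` is fit to
    the temporal-mean velocity over static-tissue voxels by weighted
    least squares with weights ``1 / (variance_floor + temporal
    variance)`` per voxel; the fitted field is then subtracted from all
    timeframes everywhere.

    Returns the corrected field and the fitted coefficients, shape
    ``(n_terms, 3)`` on the centered/scaled monomial basis.
    """
    if not grids_match(static.affine, fld.affine, static.data.shape, fld.shape):
        raise ValueError("static-tissue mask grid does not match velocity grid")
    n_terms = n_polynomial_terms(order)
    sel = static.data.reshape(-1)
    if int(sel.sum()) < 10 * n_terms:
        raise ValueError(
            f"static mask has {int(sel.sum())} voxels; "
            f"need at least {10 * n_terms} for an order-{order} fit"
        )
    scaled = _scaled_coordinates(fld.shape, fld.affine)
    X = polynomial_design(scaled[sel], order)
    flat = fld.velocity.reshape(-1, fld.n_timeframes, 3)
    coeffs = np.empty((n_terms, 3))
    for c in range(3):
        series = flat[sel, :, c]
        y = series.mean(axis=1)
        w = 1.0 / (variance_floor + series.var(axis=1, ddof=0))
        sw = np.sqrt(w)
        beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if rank < n_terms:
            raise ValueError(
                "rank-deficient polynomial design; enlarge the static mask "
                "or lower the fit order"
            )
        coeffs[:, c] = beta
    fitted = polynomial_design(scaled, order) @ coeffs  # (nvox, 3)
    fitted = fitted.reshape(*fld.shape, 1, 3)
    return replace(fld, velocity=fld.velocity - fitted), coeffs


def find_peak_systole(fld: VelocityField4D, lumen: MaskVolume) -> int:
    """Timeframe with maximum lumen-mean velocity magnitude (earliest tie)."""
    if not grids_match(lumen.affine, fld.affine, lumen.data.shape, fld.shape):
        raise ValueError("lumen mask grid does not match velocity grid")
    if lumen.n_voxels == 0:
        raise ValueError("lumen mask is empty")
    speed = fld.speed()[lumen.data]  # (n_lumen, nt)
    return int(np.argmax(speed.mean(axis=0)))
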
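"""Shared fixtures: phantoms with analytic ground truth, reused across tests.

Session-scoped fixtures build each phantom once; problem sizes are kept
small (short vessels, reduced timeframe counts) so the whole suite runs
in minutes on one CPU.
"""

import numpy as np
import pytest

from aortawss import (
    ViscosityModel,
    WSSConfig,
    compute_hemodynamic_maps,
    compute_wss_field,
    extract_surface,
)
from aortawss.phantom import FlowWaveform, PhantomSpec, build_phantom

#: closed-form Poiseuille wall shear 4 mu Q / (pi R^3) for the fixture below
POISEUILLE_RADIUS_MM = 16.0
POISEUILLE_MU = 0.0035


def poiseuille_flow_for_tau(tau_Pa, radius_mm=POISEUILLE_RADIUS_MM, mu=POISEUILLE_MU):
    """Invert tau = 4 mu Q / (pi R^3) for the flow rate Q (m^3/s)."""
    return tau_Pa * np.pi * (radius_mm * 1e-3) ** 3 / (4.0 * mu)


def tube_interior(mesh, radius_mm, z_lo=20.0, z_hi=80.0, missing=None):
    """Nodes on the cylindrical wall away from the end caps."""
    z = mesh.nodes[:, 2]
    axis_dist = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    sel = (z > z_lo) & (z < z_hi) & (axis_dist > 0.8 * radius_mm)
    if missing is not None:
        sel &= ~missing
    return sel


@pytest.fixture(scope="session")
def poiseuille_study():
    """Steady phantom (R = 16 mm, 2.5 mm voxels) with tau_w = 0.4456 Pa,
    analyzed with the constant-viscosity estimator."""
    tau = 0.4456
    wf = FlowWaveform(1.0, [(0, poiseuille_flow_for_tau(tau))])
    spec = PhantomSpec(
        radius_mm=POISEUILLE_RADIUS_MM,
        length_mm=100.0,
        waveform=wf,
        spacing_mm=2.5,
        n_timeframes=3,
        noise_sd_cm_s=0.0,
        venc_cm_s=150.0,
    )
    ds = build_phantom(spec)
    mesh = extract_surface(ds.lumen)
    wss = compute_wss_field(
        ds.field, mesh, WSSConfig(), ViscosityModel.newtonian(POISEUILLE_MU), "elderly"
    )
    maps = compute_hemodynamic_maps(wss)
    tube = tube_interior(mesh, POISEUILLE_RADIUS_MM, missing=wss.missing)
    return {"ds": ds, "mesh": mesh, "wss": wss, "maps": maps, "tube": tube}


@pytest.fixture(scope="session")
def womersley_study():
    """Pulsatile k=0 + k=1 phantom in the resolvable low-Womersley regime.

    A glycerol-like test fluid (mu = 0.1 Pa s, rho = 1100 kg/m^3) gives
    alpha ~ 3, so the oscillatory boundary layer spans several voxels
    and the wall-gradient estimator operates within its assumptions.
    """
    mu, rho, R = 0.1, 1100.0, 12.0
    wf = FlowWaveform(1.0, [(0, 8.0e-5), (1, 1.2e-4)])
    spec = PhantomSpec(
        radius_mm=R,
        length_mm=100.0,
        waveform=wf,
        mu_Pa_s=mu,
        rho_kg_m3=rho,
        spacing_mm=2.5,
        n_timeframes=40,
        noise_sd_cm_s=0.0,
        venc_cm_s=200.0,
    )
    ds = build_phantom(spec)
    mesh = extract_surface(ds.lumen)
    wss = compute_wss_field(
        ds.field, mesh, WSSConfig(), ViscosityModel.newtonian(mu), "elderly"
    )
    maps = compute_hemodynamic_maps(wss)
    tube = tube_interior(mesh, R, missing=wss.missing)
    return {"ds": ds, "mesh": mesh, "wss": wss, "maps": maps, "tube": tube,
            "radius_mm": R, "mu": mu, "rho": rho}


@pytest.fixture(scope="session")
def pulsatile_phantom():
    """Blood-like pulsatile phantom used for flow/segment tests."""
    wf = FlowWaveform(1.0, [(0, 7.0e-5), (1, 8.0e-5)])
    spec = PhantomSpec(
        radius_mm=10.0,
        length_mm=100.0,
        waveform=wf,
        spacing_mm=2.5,
        n_timeframes=20,
        noise_sd_cm_s=0.0,
        venc_cm_s=150.0,
    )
    return build_phantom(spec)
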
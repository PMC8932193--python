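"""Viscosity model, WSS estimator and the TAWSS/OSI/RRT maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortawss import (
    MaskVolume,
    SurfaceMesh,
    VelocityField4D,
    ViscosityModel,
    WSSConfig,
    WSSVectorField,
    carreau_yasuda,
    compute_hemodynamic_maps,
    compute_wss_field,
    extract_surface,
)


class TestCarreauYasuda:
    def test_infinite_shear_limit(self):
        # with the default blood parameters the shear-thinning term decays
        # like (lambda g)^(n-1); at 1e6/s it is ~1e-3 of mu_inf, at 1e8/s
        # it is below 1e-4
        assert carreau_yasuda(1e6) == pytest.approx(0.0035, rel=1.5e-3)
        assert carreau_yasuda(1e8) == pytest.approx(0.0035, rel=1e-4)

    def test_zero_shear_is_mu_zero(self):
        model = ViscosityModel()
        assert carreau_yasuda(0.0, model) == model.mu_zero_Pa_s

    def test_physiological_value(self):
        # mu(100/s) for mu0=0.056, lambda=3.313, a=2, n=0.3568, evaluated
        # by hand from the closed form
        assert carreau_yasuda(100.0) == pytest.approx(4.7572e-3, rel=1e-3)

    def test_monotone_non_increasing(self):
        g = np.logspace(-3, 5, 200)
        mu = carreau_yasuda(g)
        assert np.all(np.diff(mu) <= 0)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            carreau_yasuda(-1.0)

    def test_newtonian_constructor(self):
        m = ViscosityModel.newtonian(0.0035)
        assert carreau_yasuda(0.0, m) == carreau_yasuda(1e4, m) == 0.0035

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ViscosityModel(mu_inf_Pa_s=0.01, mu_zero_Pa_s=0.005)
        with pytest.raises(ValueError):
            ViscosityModel(n_index=1.5)


def box_field(g_per_s=100.0, n=16, sp=2.0):
    """Box lumen with velocity parallel to the wall, linear in the
    distance from the +x face: an exactly recoverable shear profile."""
    lumen = np.zeros((n, n, n), dtype=bool)
    lumen[2:-2, 2:-2, 2:-2] = True
    affine = np.diag([sp, sp, sp, 1.0])
    x_wall = ((n - 3) + 0.5) * sp  # 0.5-isosurface of the +x face
    x = np.arange(n) * sp
    depth = np.clip(x_wall - x, 0.0, None)  # mm from the +x wall
    v = np.zeros((n, n, n, 2, 3))
    # slope g [1/s] = 10 * (cm/s per mm)
    v[..., 2] = (g_per_s / 10.0) * depth[:, None, None, None]
    v[~lumen] = 0.0
    fld = VelocityField4D(v, affine, 1.0, 150.0, np.array([0.0, 0.5]))
    return fld, MaskVolume(lumen, affine)


class TestWSSEstimator:
    def test_zero_field_gives_zero_wss(self, poiseuille_study):
        ds = poiseuille_study["ds"]
        mesh = poiseuille_study["mesh"]
        zero = VelocityField4D(
            np.zeros_like(ds.field.velocity), ds.field.affine,
            ds.field.period_s, ds.field.venc_cm_s, ds.field.timeframe_times_s,
        )
        wss = compute_wss_field(zero, mesh, cohort="elderly")
        assert np.nanmax(np.abs(wss.values_Pa)) == 0.0

    def test_linear_profile_exact(self):
        # v parallel to a flat wall, slope 100/s, constant mu 0.0035
        # -> |WSS| = 0.35 Pa; the cubic spline reproduces a line exactly
        fld, lumen = box_field(g_per_s=100.0)
        mesh = extract_surface(lumen)
        # interior nodes of the +x face, away from edges
        on_face = (np.abs(mesh.outward_normals[:, 0] - 1.0) < 1e-9)
        mid = np.all(np.abs(mesh.nodes[:, 1:] - mesh.nodes[:, 1:].mean(0)) < 6.0,
                     axis=1)
        sel = on_face & mid
        assert sel.sum() > 10
        wss = compute_wss_field(
            fld, mesh, WSSConfig(), ViscosityModel.newtonian(0.0035), "elderly"
        )
        mag = wss.magnitude()[sel]
        np.testing.assert_allclose(mag, 0.35, rtol=1e-9)

    def test_poiseuille_within_estimator_tolerance(self, poiseuille_study):
        maps = poiseuille_study["maps"]
        tube = poiseuille_study["tube"]
        truth = poiseuille_study["ds"].truth
        est = np.nanmean(maps.tawss_Pa[tube])
        assert est == pytest.approx(truth.tawss_Pa, rel=0.20)

    def test_tangency(self, poiseuille_study):
        mesh = poiseuille_study["mesh"]
        wss = poiseuille_study["wss"]
        dot = np.abs(np.einsum("ntc,nc->nt", np.nan_to_num(wss.values_Pa),
                               mesh.outward_normals))
        mag = np.nan_to_num(wss.magnitude())
        assert np.all(dot <= 1e-9 * np.maximum(mag, 1e-300) + 1e-12)

    def test_unknown_cohort_rejected(self, poiseuille_study):
        with pytest.raises(ValueError, match="cohort"):
            compute_wss_field(
                poiseuille_study["ds"].field, poiseuille_study["mesh"],
                cohort="unknown",
            )

    def test_nodes_outside_grid_flagged_missing(self):
        fld, lumen = box_field()
        mesh = SurfaceMesh(
            nodes=np.array([[200.0, 200.0, 200.0], [14.0, 14.0, 14.0],
                            [14.0, 16.0, 14.0]]),
            triangles=np.array([[0, 1, 2]]),
            outward_normals=np.array([[1.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]]),
            node_area_mm2=np.ones(3),
        )
        wss = compute_wss_field(fld, mesh, cohort="elderly")
        assert wss.missing[0] and not wss.missing[1]
        assert np.all(np.isnan(wss.values_Pa[0]))


def series_field(values, times=None, period=1.0):
    values = np.asarray(values, dtype=np.float64)
    nt = values.shape[1]
    if times is None:
        times = np.arange(nt) * period / nt
    return WSSVectorField(
        values_Pa=values,
        missing=np.zeros(values.shape[0], dtype=bool),
        timeframe_times_s=np.asarray(times, dtype=np.float64),
        period_s=period,
    )


class TestHemodynamicMaps:
    def test_constant_vector(self):
        v = np.tile([1.2, 0.0, 0.0], (1, 8, 1))
        maps = compute_hemodynamic_maps(series_field(v))
        assert maps.tawss_Pa[0] == pytest.approx(1.2, rel=1e-12)
        assert maps.osi[0] == 0.0
        assert maps.rrt[0] == pytest.approx(1.0 / 1.2, rel=1e-12)

    def test_perfect_reversal(self):
        v = np.zeros((1, 8, 3))
        v[0, :4] = [0.7, 0.1, 0.0]
        v[0, 4:] = [-0.7, -0.1, 0.0]
        maps = compute_hemodynamic_maps(series_field(v))
        assert maps.osi[0] == pytest.approx(0.5, abs=1e-12)
        assert maps.rrt_capped[0]
        assert maps.rrt[0] == WSSConfig().rrt_cap

    def test_partial_reversal_rrt(self):
        # two half-cycle vectors of magnitude 0.5 at an angle chosen so
        # OSI = 0.1 and TAWSS = 0.5, hence RRT = 1/(0.8 * 0.5) = 2.5
        cos_t = 0.28
        sin_t = np.sqrt(1.0 - cos_t**2)
        v = np.zeros((1, 2, 3))
        v[0, 0] = [0.5, 0.0, 0.0]
        v[0, 1] = [0.5 * cos_t, 0.5 * sin_t, 0.0]
        maps = compute_hemodynamic_maps(series_field(v))
        assert maps.tawss_Pa[0] == pytest.approx(0.5, rel=1e-12)
        assert maps.osi[0] == pytest.approx(0.1, abs=1e-12)
        assert maps.rrt[0] == pytest.approx(2.5, rel=1e-12)

    def test_zero_series_defined(self):
        maps = compute_hemodynamic_maps(series_field(np.zeros((1, 6, 3))))
        assert maps.osi[0] == 0.0
        assert maps.rrt_capped[0]

    def test_random_series_invariants(self):
        """OSI in [0, 0.5] and the RRT identity on 1000 random series."""
        rng = np.random.default_rng(12345)
        v = rng.normal(size=(1000, 16, 3))
        maps = compute_hemodynamic_maps(series_field(v))
        assert np.all(maps.osi >= 0.0) and np.all(maps.osi <= 0.5)
        free = ~maps.rrt_capped
        ident = maps.rrt[free] * (1 - 2 * maps.osi[free]) * maps.tawss_Pa[free]
        np.testing.assert_allclose(ident, 1.0, rtol=1e-12)
        assert np.all(maps.rrt[free] >= 1.0 / maps.tawss_Pa[free] - 1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=3, max_value=24))
    def test_osi_bounds_property(self, seed, nt):
        rng = np.random.default_rng(seed)
        v = rng.standard_t(df=3, size=(8, nt, 3)) * rng.lognormal(size=(8, 1, 1))
        maps = compute_hemodynamic_maps(series_field(v))
        assert np.all((maps.osi >= 0.0) & (maps.osi <= 0.5))
        assert np.all(maps.tawss_Pa >= 0.0)

    def test_nonuniform_times_quadrature(self):
        # constant series must give TAWSS equal to the constant magnitude
        # under any (non-uniform) periodic sampling
        times = np.array([0.0, 0.1, 0.3, 0.35, 0.7, 0.9])
        v = np.tile([0.0, 2.0, 0.0], (1, 6, 1))
        maps = compute_hemodynamic_maps(series_field(v, times=times))
        assert maps.tawss_Pa[0] == pytest.approx(2.0, rel=1e-12)
        assert maps.osi[0] == 0.0
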
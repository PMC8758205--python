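"""Closed-form kinetics: frozen hand-computed values, identities, scaling laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from adsorbsim import kinetics as kin
from adsorbsim.constants import AVOGADRO

positive = st.floats(min_value=1e-6, max_value=1e6)


# ---------------------------------------------------------------------------
# Frozen closed-form evaluations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "func, args, expected, rtol",
    [
        (kin.stokes_einstein, (298.0, 8.9e-4, 1e-9), 2.4526e-10, 1e-4),
        (kin.radius_from_mw, (1.6605e-22, 1350.0), 3.0851e-9, 1e-4),
        (kin.gaussian_profile, (0.0, 1.0, 1e-12), 2.8209e5, 1e-4),
        (kin.gamma_langmuir_schaefer, (1.0, 1e-12, 6.022e17, 1e-10), 6.795, 1e-3),
        (kin.gamma_discrete, (1.0, 1.0, 1.0, 1.0), 1.0 / np.sqrt(np.pi), 1e-12),
        (kin.collision_rate, (1.0, 1.0, 1.0, 1.0), 2.0 / np.sqrt(np.pi), 1e-12),
        (kin.characteristic_time, (1.5055e16, 1e-12), 12.88, 1e-3),
        (kin.sam_ideal_k2, (2e-19, 6.022e23, 5e-10), 6.475e3, 1e-3),
        (kin.biosensor_k3, (2e-18, 6.022e17, 1e-10, 1e-3), 4.297e-4, 1e-3),
        (kin.nearest_neighbor_spacing, (1e24,), 1e-8, 1e-12),
        (kin.surface_flux_rate, (1.0, 1.0, 1.0, np.pi), 1.0, 1e-12),
        (kin.characteristic_time, (1.0, np.pi / 4.0), 1.0, 1e-12),
    ],
)
def test_closed_form_values(func, args, expected, rtol):
    assert float(func(*args)) == pytest.approx(expected, rel=rtol)


def test_ume_worked_example_rate():
    """Disk electrode, 10 um diameter, 25 pM, D=1e-12 m^2/s -> 0.37 1/s."""
    A = np.pi * (5e-6) ** 2
    c_b = kin.convert_concentration(25.0, "pM")
    rate = kin.initial_adsorption_rate(A, c_b, 1e-12)
    assert rate == pytest.approx(0.37, abs=0.005)


@pytest.mark.parametrize(
    "value, unit, expected",
    [
        (25.0, "pM", 1.5055e16),
        (1.0, "nM", 6.0221e17),
        (1.0, "mM", 6.02214076e23),
        (0.0, "M", 0.0),
        (2.0, "per_m3", 2.0),
        (1.0, "mol/m^3", AVOGADRO),
    ],
)
def test_convert_concentration(value, unit, expected):
    assert kin.convert_concentration(value, unit) == pytest.approx(expected, rel=1e-4)


def test_convert_concentration_unknown_unit():
    with pytest.raises(ValueError, match="unknown concentration unit"):
        kin.convert_concentration(1.0, "furlongs")


@pytest.mark.parametrize(
    "func, args",
    [
        (kin.stokes_einstein, (0.0, 1.0, 1.0)),
        (kin.stokes_einstein, (1.0, -1.0, 1.0)),
        (kin.radius_from_mw, (0.0, 1.0)),
        (kin.gaussian_profile, (0.0, 0.0, 1.0)),
        (kin.surface_flux_rate, (0.0, 1.0, 1.0, 1.0)),
        (kin.gamma_langmuir_schaefer, (-1.0, 1.0, 1.0, 1.0)),
        (kin.gamma_discrete, (0.0, 1.0, 1.0, 1.0)),
        (kin.collision_rate, (-2.0, 1.0, 1.0, 1.0)),
        (kin.nearest_neighbor_spacing, (0.0,)),
        (kin.characteristic_time, (1.0, 0.0)),
        (kin.initial_adsorption_rate, (1.0, -1.0, 1.0)),
        (kin.sam_ideal_k2, (0.0, 1.0, 1.0)),
        (kin.biosensor_k3, (1.0, 1.0, 1.0, 0.0)),
        (kin.langmuir_coverage, (-1.0, 10.0, 1.0)),
    ],
)
def test_domain_errors(func, args):
    with pytest.raises(ValueError):
        func(*args)


# ---------------------------------------------------------------------------
# Scaling laws and simple limits
# ---------------------------------------------------------------------------


def test_stokes_einstein_scaling():
    D = kin.stokes_einstein(298.0, 8.9e-4, 1e-9)
    assert kin.stokes_einstein(298.0, 8.9e-4, 2e-9) == pytest.approx(D / 2, rel=1e-14)
    assert kin.stokes_einstein(298.0, 8.9e4, 1e-9) < 1e-7 * D  # eta -> inf limit


def test_radius_mw_roundtrip_and_scaling():
    r = kin.radius_from_mw(1.6605e-22, 1350.0)
    mw_back = (4.0 / 3.0) * np.pi * r**3 * 1350.0
    assert mw_back == pytest.approx(1.6605e-22, rel=1e-12)
    assert kin.radius_from_mw(1.6605e-22, 8 * 1350.0) == pytest.approx(r / 2, rel=1e-12)


def test_gaussian_profile_normalization_and_symmetry():
    for t, D in [(1.0, 1e-12), (0.3, 2e-9)]:
        w = 12 * np.sqrt(2 * D * t)
        total, _ = quad(lambda x: kin.gaussian_profile(x, t, D), -w, w)
        assert total == pytest.approx(1.0, rel=1e-9)
    x = np.linspace(-1e-5, 1e-5, 11)
    C = kin.gaussian_profile(x, 1.0, 1e-10)
    np.testing.assert_allclose(C, C[::-1], rtol=1e-14)


def test_surface_flux_integrates_to_langmuir_schaefer():
    A, c_b, D, t = 1e-12, 6.022e17, 1e-10, 2.5
    integral, _ = quad(lambda u: kin.surface_flux_rate(u, A, c_b, D), 0, t,
                       points=[1e-12])
    assert integral == pytest.approx(
        float(kin.gamma_langmuir_schaefer(t, A, c_b, D)), rel=1e-6
    )
    # t -> 4t halves the rate
    r1 = kin.surface_flux_rate(1.0, A, c_b, D)
    assert kin.surface_flux_rate(4.0, A, c_b, D) == pytest.approx(r1 / 2, rel=1e-14)


def test_gamma_langmuir_schaefer_sqrt_t_scaling():
    A, c_b, D = 2.0, 3.0, 5e-10
    assert float(kin.gamma_langmuir_schaefer(0.0, A, c_b, D)) == 0.0
    g1 = float(kin.gamma_langmuir_schaefer(1.0, A, c_b, D))
    g4 = float(kin.gamma_langmuir_schaefer(4.0, A, c_b, D))
    assert g4 == pytest.approx(2 * g1, rel=1e-14)


def test_langmuir_coverage_limits():
    assert float(kin.langmuir_coverage(0.0, 150, 0.43)) == 0.0
    assert float(kin.langmuir_coverage(1e9, 150, 0.43)) == pytest.approx(150.0)
    assert float(kin.langmuir_coverage(1.0 / 0.43, 150, 0.43)) == pytest.approx(
        150 * (1 - np.exp(-1)), rel=1e-12
    )


# ---------------------------------------------------------------------------
# Discrete-vs-continuum identities
# ---------------------------------------------------------------------------


@given(A=positive, c_b=positive, D=positive, dt=positive)
@settings(max_examples=200, deadline=None)
def test_two_fold_gap_and_mirror(A, c_b, D, dt):
    """Continuum law at t=dt is exactly twice the single-PDF count; the
    mirror factor doubles the single-PDF count; <r>*dt equals the mirrored
    count."""
    continuum = float(kin.gamma_langmuir_schaefer(dt, A, c_b, D))
    single_pdf = float(kin.gamma_discrete(dt, A, c_b, D, mirror=False))
    mirrored = float(kin.gamma_discrete(dt, A, c_b, D, mirror=True))
    assert continuum == pytest.approx(2 * single_pdf, rel=1e-13)
    assert mirrored == pytest.approx(2 * single_pdf, rel=1e-13)
    assert float(kin.collision_rate(dt, A, c_b, D)) * dt == pytest.approx(
        mirrored, rel=1e-13
    )


def test_collision_rate_quarter_dt():
    r1 = float(kin.collision_rate(1.0, 1.0, 1.0, 1.0))
    assert float(kin.collision_rate(4.0, 1.0, 1.0, 1.0)) == pytest.approx(
        r1 / 2, rel=1e-14
    )


@given(A=positive, c_b=positive, D=positive)
@settings(max_examples=200, deadline=None)
def test_initial_rate_three_routes_agree(A, c_b, D):
    """Collision rate at the characteristic time, the d0^2-patch turnover,
    and the closed form (4/pi)*A*c_b^(4/3)*D are one identity."""
    dtc = kin.characteristic_time(c_b, D)
    via_collision_rate = float(kin.collision_rate(dtc, A, c_b, D))
    d0 = kin.nearest_neighbor_spacing(c_b)
    via_patch_turnover = (A / d0**2) / dtc
    closed = kin.initial_adsorption_rate(A, c_b, D)
    assert via_collision_rate == pytest.approx(closed, rel=1e-9)
    assert via_patch_turnover == pytest.approx(closed, rel=1e-9)


def test_initial_rate_concentration_order():
    r = kin.initial_adsorption_rate(1.0, 1.0, 1.0)
    assert kin.initial_adsorption_rate(1.0, 2.0, 1.0) == pytest.approx(
        2 ** (4 / 3) * r, rel=1e-12
    )
    # per-site variants share the scaling: k2 is 4/3-order, k3 first-order
    assert kin.sam_ideal_k2(1.0, 8.0, 1.0) == pytest.approx(
        16 * kin.sam_ideal_k2(1.0, 1.0, 1.0), rel=1e-12
    )
    assert kin.biosensor_k3(1.0, 2.0, 1.0, 1.0) == pytest.approx(
        2 * kin.biosensor_k3(1.0, 1.0, 1.0, 1.0), rel=1e-12
    )


def test_per_site_rates_equal_ensemble_forms():
    a, c_b, D, dt = 3e-19, 4e22, 7e-10, 2e-3
    assert kin.sam_ideal_k2(a, c_b, D) == pytest.approx(
        kin.initial_adsorption_rate(a, c_b, D), rel=1e-14
    )
    assert kin.biosensor_k3(a, c_b, D, dt) == pytest.approx(
        float(kin.collision_rate(dt, a, c_b, D)), rel=1e-14
    )


def test_characteristic_spacing_consistency():
    """Mean half-Gaussian excursion sqrt(4*D*dtc/pi) equals the
    nearest-neighbor spacing c_b^(-1/3), and the moment-ratio identity
    holds by independent quadrature."""
    c_b, D = 2.5e20, 3e-10
    dtc = kin.characteristic_time(c_b, D)
    d0 = kin.nearest_neighbor_spacing(c_b)
    assert np.sqrt(4 * D * dtc / np.pi) == pytest.approx(d0, rel=1e-12)

    s2 = 4 * D * dtc  # the z-integrals use exp(-z^2 / (4 D dt))
    w = 12 * np.sqrt(s2)
    num, _ = quad(lambda z: z * np.exp(-(z**2) / s2), 0, w)
    den, _ = quad(lambda z: np.exp(-(z**2) / s2), 0, w)
    assert num / den == pytest.approx(np.sqrt(4 * D * dtc / np.pi), rel=1e-9)


def test_d0_cube_root_scaling():
    assert kin.nearest_neighbor_spacing(8e24) == pytest.approx(
        kin.nearest_neighbor_spacing(1e24) / 2, rel=1e-12
    )
    assert kin.characteristic_time(8.0, 1.0) == pytest.approx(
        kin.characteristic_time(1.0, 1.0) / 4, rel=1e-12
    )


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=50, deadline=None)
def test_unit_homogeneity(scale):
    """Rescaling all lengths by a common factor (m -> cm style) leaves the
    dimensionless ratio of the initial rate to the collision rate at the
    characteristic time unchanged."""
    A, c_b, D, = 2e-11, 3e16, 1.3e-12
    A2, c2, D2 = A * scale**2, c_b / scale**3, D * scale**2
    ratio1 = kin.initial_adsorption_rate(A, c_b, D) / float(
        kin.collision_rate(kin.characteristic_time(c_b, D), A, c_b, D)
    )
    ratio2 = kin.initial_adsorption_rate(A2, c2, D2) / float(
        kin.collision_rate(kin.characteristic_time(c2, D2), A2, c2, D2)
    )
    assert ratio1 == pytest.approx(ratio2, rel=1e-9)


# ---------------------------------------------------------------------------
# Ward–Tordai
# ---------------------------------------------------------------------------


class TestWardTordai:
    A, c_b, D, t = 1e-12, 1e20, 1e-10, 1.5

    def history(self, level):
        return kin.SubsurfaceHistory.constant(level, 2.0)

    def test_zero_history_reduces_to_langmuir_schaefer(self):
        g = kin.gamma_ward_tordai(self.t, self.A, self.c_b, self.D, self.history(0.0))
        ls = float(kin.gamma_langmuir_schaefer(self.t, self.A, self.c_b, self.D))
        assert g == pytest.approx(ls, rel=1e-6)

    def test_bulk_history_cancels_identically(self):
        g = kin.gamma_ward_tordai(
            self.t, self.A, self.c_b, self.D, self.history(self.c_b)
        )
        ls = float(kin.gamma_langmuir_schaefer(self.t, self.A, self.c_b, self.D))
        assert abs(g) < 1e-9 * ls

    def test_half_history_is_linear(self):
        g = kin.gamma_ward_tordai(
            self.t, self.A, self.c_b, self.D, self.history(self.c_b / 2)
        )
        ls = float(kin.gamma_langmuir_schaefer(self.t, self.A, self.c_b, self.D))
        assert g == pytest.approx(ls / 2, rel=1e-6)

    def test_history_must_cover_t(self):
        with pytest.raises(ValueError, match="history covers"):
            kin.gamma_ward_tordai(3.0, self.A, self.c_b, self.D, self.history(0.0))

    def test_smooth_history_against_dense_quadrature(self):
        """Linearly ramping subsurface concentration vs brute-force quadrature
        of the singular kernel."""
        times = np.linspace(0.0, 2.0, 2001)
        hist = kin.SubsurfaceHistory(times, self.c_b * times / 2.0)
        g = kin.gamma_ward_tordai(self.t, self.A, self.c_b, self.D, hist)
        # independent: integrate c(tau)/sqrt(t-tau) directly with quad
        val, _ = quad(
            lambda tau: (self.c_b * tau / 2.0) / np.sqrt(self.t - tau),
            0.0,
            self.t,
            points=[self.t],
            limit=200,
        )
        expected = float(
            kin.gamma_langmuir_schaefer(self.t, self.A, self.c_b, self.D)
        ) - self.A * np.sqrt(self.D / np.pi) * val
        assert g == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def test_diffusion_params_derives_d_and_r():
    p = kin.DiffusionParams(T=298.0, eta=8.9e-4, Mw=1.6605e-22, rho=1350.0)
    assert p.r == pytest.approx(3.0851e-9, rel=1e-4)
    assert p.D == pytest.approx(
        kin.stokes_einstein(298.0, 8.9e-4, p.r), rel=1e-12
    )
    with pytest.raises(ValueError):
        kin.DiffusionParams(D=-1e-10)


def test_geometry_and_observation_scheme_invariants():
    g = kin.Geometry(A=2.0, L=3.0)
    assert g.V == pytest.approx(6.0)
    with pytest.raises(ValueError):
        kin.Geometry(A=0.0, L=1.0)
    s = kin.ObservationScheme(dt=0.1, n_sub=4)
    assert s.dt_sub == pytest.approx(0.025)
    with pytest.raises(ValueError):
        kin.ObservationScheme(dt=0.1, n_sub=0)
    with pytest.raises(ValueError):
        kin.ObservationScheme(dt=-0.1)


def test_concentration_and_rateset_types():
    c = kin.Concentration.from_value(1.0, "mM")
    assert c.molar == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        kin.RateSet(r_mean=-1.0)


def test_subsurface_history_validation():
    with pytest.raises(ValueError, match="increasing from 0"):
        kin.SubsurfaceHistory(np.array([0.1, 0.2]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="nonnegative"):
        kin.SubsurfaceHistory(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
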
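"""Analytics oracles: fields, profiles, fits, time series, bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stokesflow import postprocess as pp
from stokesflow.errors import (DegenerateTransform, DomainError, FitError,
                               UndefinedCorrelation)
from stokesflow.fem import DivergenceSource, StokesSystem, VelocityField
from stokesflow.geometry import disk_mesh
from stokesflow.synthetic import analytic_flow

DT = 0.4


@pytest.fixture(scope="module")
def disk_space():
    return StokesSystem(disk_mesh(5.0, 0.35, center=(0.0, 0.0)), 1.0).space


def _field_from_flow(space, flow):
    return VelocityField(space, np.asarray(flow.u(space.coords)).T)


class TestVorticity:
    def test_uniform_flow_zero(self, disk_space):
        u = VelocityField(disk_space, np.tile([[0.4], [0.1]],
                                              (1, disk_space.n_dofs)))
        np.testing.assert_allclose(pp.vorticity(u), 0.0, atol=1e-10)

    def test_rigid_rotation_gives_2omega(self, disk_space):
        omega = 0.05
        flow = analytic_flow("rotation", omega=omega, center=(0.0, 0.0),
                             radius=5.0)
        v = pp.vorticity(_field_from_flow(disk_space, flow))
        np.testing.assert_allclose(v, 2 * omega, rtol=1e-8)

    def test_poiseuille_vorticity_linear_in_y(self, disk_space):
        U, H = 1.0, 8.0
        flow = analytic_flow("poiseuille", U=U, H=H, L=20.0,
                             center=(0.0, 0.0))
        v = pp.vorticity(_field_from_flow(disk_space, flow))
        expected = 8 * U * disk_space.mesh.nodes[:, 1] / H ** 2
        np.testing.assert_allclose(v, expected, atol=1e-8 * 8 * U / H)


class TestStreamlines:
    def test_uniform_flow_straight_lines(self, disk_space):
        u = VelocityField(disk_space, np.tile([[0.5], [0.0]],
                                              (1, disk_space.n_dofs)))
        (line,) = pp.streamlines(u, [(-3.0, 0.5)], max_arc_length=2.0)
        assert len(line) > 2
        np.testing.assert_allclose(line[:, 1], 0.5, atol=1e-6)

    def test_rotation_orbit_closes(self, disk_space):
        omega = 0.1
        flow = analytic_flow("rotation", omega=omega, center=(0.0, 0.0),
                             radius=5.0)
        u = _field_from_flow(disk_space, flow)
        R = 2.5
        period = 2 * np.pi / omega
        (line,) = pp.streamlines(u, [(R, 0.0)], t_max=period,
                                 max_arc_length=3 * np.pi * R, tol=1e-10)
        gap = np.linalg.norm(line[-1] - line[0])
        assert gap < 1e-4 * R

    def test_zero_field_stalls(self, disk_space):
        u = VelocityField(disk_space, np.zeros((2, disk_space.n_dofs)))
        (line,) = pp.streamlines(u, [(1.0, 1.0)])
        assert np.linalg.norm(line[-1] - line[0]) < 1e-12

    def test_outside_seed_skipped(self, disk_space):
        u = VelocityField(disk_space, np.zeros((2, disk_space.n_dofs)))
        lines = pp.streamlines(u, [(100.0, 100.0), (0.0, 0.0)])
        assert len(lines[0]) == 0
        assert len(lines[1]) > 0


class TestLineProfile:
    def test_constant_field_constant_samples(self, disk_space):
        s, vals = pp.line_profile(lambda pts: np.full(len(pts), 3.0),
                                  (-2, 0), (2, 0), 11)
        np.testing.assert_allclose(vals, 3.0)
        np.testing.assert_allclose(s, np.linspace(0, 1, 11))

    def test_linear_field_sampled_exactly(self, disk_space):
        u = VelocityField(disk_space,
                          np.stack([disk_space.coords[:, 0] * 0.2,
                                    np.zeros(disk_space.n_dofs)]))
        s, vals = pp.line_profile(lambda pts: np.atleast_2d(u.at(pts))[0],
                                  (-3, 0), (3, 0), 13)
        expected = 0.2 * np.linspace(-3, 3, 13)
        np.testing.assert_allclose(vals, expected, atol=1e-10)

    def test_two_samples_are_endpoints(self):
        s, vals = pp.line_profile(lambda pts: pts[:, 0], (1.0, 0.0),
                                  (2.0, 0.0), 2)
        np.testing.assert_allclose(vals, [1.0, 2.0])

    def test_segment_leaving_domain_rejected(self, disk_space):
        u = VelocityField(disk_space, np.zeros((2, disk_space.n_dofs)))

        class FieldWrapper:
            space = disk_space

            def at(self, pts):
                return u.at(pts)

        with pytest.raises(DomainError):
            pp.line_profile(FieldWrapper(), (0, 0), (20, 0), 11)


class TestPoiseuilleFit:
    def test_exact_parabola(self):
        s = np.linspace(-1, 1, 21)
        fit = pp.fit_poiseuille(s, 1 - s ** 2)
        assert fit.v_max == pytest.approx(1.0, abs=1e-12)
        assert fit.width == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_parabola_width_within_5pct(self):
        rng = np.random.default_rng(5)
        s = np.linspace(-1, 1, 41)
        v = 1 - s ** 2 + rng.normal(0, 0.05, size=s.shape)
        fit = pp.fit_poiseuille(s, v)
        assert fit.width == pytest.approx(2.0, rel=0.05)
        assert fit.r_squared > 0.98

    def test_linear_profile_width_undefined(self):
        s = np.linspace(0, 1, 11)
        fit = pp.fit_poiseuille(s, 2 + 0.1 * s)
        assert not fit.width_defined
        assert fit.width is None


class TestSigmoid:
    TRUE = pp.SigmoidParams(a=10.0, b=8.0, c=0.5, d=2.0)

    def test_noiseless_recovery(self):
        s = np.linspace(0, 1, 50)
        p = self.TRUE.evaluate(s)
        fit = pp.fit_sigmoid(s, p)
        for got, want in zip(fit, self.TRUE):
            assert got == pytest.approx(want, abs=1e-6)

    def test_half_range_at_position_c(self):
        s = np.linspace(0, 1, 50)
        fit = pp.fit_sigmoid(s, self.TRUE.evaluate(s))
        assert fit.evaluate(fit.c) == pytest.approx(fit.d + fit.a / 2, rel=1e-9)

    def test_flat_profile_rejected(self):
        with pytest.raises(FitError):
            pp.fit_sigmoid(np.linspace(0, 1, 20), np.full(20, 3.0))

    def test_collapse_is_identity_on_exact_sigmoid(self):
        s = np.linspace(0.05, 0.95, 40)
        p = self.TRUE.evaluate(s)
        sv, collapsed, dropped = pp.collapse_sigmoid(s, p, self.TRUE)
        assert dropped == 0
        np.testing.assert_allclose(collapsed, sv, atol=1e-10)

    @given(a=st.floats(1.0, 50.0), b=st.floats(2.0, 20.0),
           c=st.floats(0.2, 0.8), d=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_two_sigmoids_collapse_onto_the_same_unitary_line(self, a, b, c, d):
        params = pp.SigmoidParams(a=a, b=b, c=c, d=d)
        s = np.linspace(0.05, 0.95, 30)
        sv, collapsed, _ = pp.collapse_sigmoid(s, params.evaluate(s), params)
        np.testing.assert_allclose(collapsed, sv, atol=1e-8)

    def test_boundary_sample_dropped_and_counted(self):
        s = np.linspace(0, 1, 20)
        p = self.TRUE.evaluate(s)
        p[3] = self.TRUE.d  # exactly at the lower asymptote
        sv, collapsed, dropped = pp.collapse_sigmoid(s, p, self.TRUE)
        assert dropped == 1
        assert len(sv) == 19

    def test_all_samples_outside_range_rejected(self):
        s = np.linspace(0, 1, 10)
        with pytest.raises(DegenerateTransform):
            pp.collapse_sigmoid(s, np.full(10, -50.0), self.TRUE)


class TestClusterSigmoidParams:
    def test_separated_groups_perfectly_clustered(self):
        rng = np.random.default_rng(8)
        g1 = [pp.SigmoidParams(a=10 + rng.normal(0, 0.3),
                               b=8 + rng.normal(0, 0.3),
                               c=0.5 + rng.normal(0, 0.02),
                               d=2 + rng.normal(0, 0.3)) for _ in range(12)]
        g2 = [pp.SigmoidParams(a=30 + rng.normal(0, 0.3),
                               b=8 + rng.normal(0, 0.3),
                               c=0.5 + rng.normal(0, 0.02),
                               d=12 + rng.normal(0, 0.3)) for _ in range(12)]
        scores, labels, diag = pp.cluster_sigmoid_params(g1 + g2, 2, seed=0)
        assert len(set(labels[:12])) == 1
        assert len(set(labels[12:])) == 1
        assert labels[0] != labels[12]
        assert not diag["degenerate"]

    def test_k1_single_label(self):
        params = [pp.SigmoidParams(a=i, b=1, c=0.5, d=0) for i in range(5)]
        _, labels, _ = pp.cluster_sigmoid_params(params, 1, seed=0)
        assert set(labels) == {0}

    def test_identical_sets_flagged_degenerate(self):
        params = [pp.SigmoidParams(a=1, b=2, c=0.5, d=0)] * 6
        _, _, diag = pp.cluster_sigmoid_params(params, 2, seed=0)
        assert diag["degenerate"]

    def test_bad_k_rejected(self):
        params = [pp.SigmoidParams(a=1, b=2, c=0.5, d=0)] * 3
        with pytest.raises(ValueError):
            pp.cluster_sigmoid_params(params, 5, seed=0)


class TestButterworth:
    def test_constant_series_unchanged(self):
        out = pp.butterworth_lowpass(np.full(200, 4.2), cutoff=0.5, dt=DT)
        np.testing.assert_allclose(out, 4.2, atol=1e-9)

    def test_stopband_attenuation(self):
        # 10x above cutoff: forward-backward order-4 response leaves < 1%
        dt = 0.01
        t = np.arange(0, 20, dt)
        cutoff = 1.0
        x = np.sin(2 * np.pi * 10 * cutoff * t)
        y = pp.butterworth_lowpass(x, cutoff, dt)
        assert np.abs(y[200:-200]).max() < 0.01

    def test_passband_preserved(self):
        dt = 0.01
        t = np.arange(0, 100, dt)
        cutoff = 1.0
        x = np.sin(2 * np.pi * (cutoff / 10) * t)
        y = pp.butterworth_lowpass(x, cutoff, dt)
        assert np.abs(y[1000:-1000]).max() == pytest.approx(1.0, rel=0.02)

    def test_zero_phase(self):
        dt = 0.1
        t = np.arange(0, 50, dt)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = pp.butterworth_lowpass(x, 0.5, dt)
        assert np.argmax(y[:300]) == pytest.approx(np.argmax(x[:300]), abs=1)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.butterworth_lowpass(np.zeros(50), cutoff=2.0, dt=DT)


class TestCcfLag:
    def test_constructed_three_sample_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = np.roll(x, 3)  # y delayed by 3 samples: x precedes y
        lag, peak = pp.ccf_lag(x, y, DT)
        assert lag == pytest.approx(3 * DT)
        assert peak == pytest.approx(1.0, abs=0.05)

    def test_self_correlation_zero_lag(self):
        x = np.sin(np.arange(100) * 0.3)
        lag, peak = pp.ccf_lag(x, x, DT)
        assert lag == 0.0
        assert peak == pytest.approx(1.0, rel=1e-6)

    def test_anticorrelated_pair_reports_negative_peak(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        lag, peak = pp.ccf_lag(x, -x, DT, max_lag=2.0)
        assert peak < 0.5  # the true (negative) correlation at zero lag is -1

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=150)
        y = np.roll(x, 5) + 0.1 * rng.normal(size=150)
        lag_xy, _ = pp.ccf_lag(x, y, DT)
        lag_yx, _ = pp.ccf_lag(y, x, DT)
        assert lag_xy == -lag_yx

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelation):
            pp.ccf_lag(np.ones(50), np.arange(50.0), DT)


class TestDominantPeriods:
    def test_two_component_series_recovered(self):
        # periods matching the reported single-cell decomposition
        t = np.arange(0, 60, DT)
        series = 3.0 + 1.5 * np.cos(2 * np.pi * t / 8.1) \
            + 0.8 * np.cos(2 * np.pi * t / 3.6)
        est = pp.dominant_periods(series, DT, 2)
        bin_res = 1.0 / (len(t) * DT)  # frequency resolution
        for target in (8.1, 3.6):
            got = est.periods[np.argmin(np.abs(est.periods - target))]
            assert abs(1 / got - 1 / target) <= bin_res

    def test_constant_series_has_no_components(self):
        est = pp.dominant_periods(np.full(64, 2.0), DT, 2)
        assert est.amplitudes.size == 0 or np.all(est.amplitudes < 1e-12)

    def test_single_cosine_period_5s(self):
        t = np.arange(0, 40, DT)
        series = np.cos(2 * np.pi * t / 5.0)
        est = pp.dominant_periods(series, DT, 1)
        bin_res = 1.0 / (len(t) * DT)
        assert abs(1 / est.periods[0] - 1 / 5.0) <= bin_res

    def test_invariant_to_constant_offset(self):
        t = np.arange(0, 40, DT)
        series = np.cos(2 * np.pi * t / 5.0)
        e1 = pp.dominant_periods(series, DT, 2)
        e2 = pp.dominant_periods(series + 17.0, DT, 2)
        np.testing.assert_allclose(e1.periods, e2.periods)
        np.testing.assert_allclose(e1.amplitudes, e2.amplitudes, atol=1e-12)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pp.dominant_periods(np.arange(8.0), DT, 10)


class TestPeriodMixture:
    def test_two_population_means_recovered(self):
        # component values matching the reported population analysis
        rng = np.random.default_rng(17)
        draws = np.concatenate([rng.normal(4.6, 1.1, 100),
                                rng.normal(7.9, 0.4, 100)])
        means, sds, weights, resid, diag = pp.fit_period_mixture(draws, 2)
        assert means[0] == pytest.approx(4.6, abs=0.3)
        assert means[1] == pytest.approx(7.9, abs=0.3)

    def test_single_cluster_mean(self):
        rng = np.random.default_rng(18)
        draws = rng.normal(5.0, 0.2, 60)
        means, _, _, _, _ = pp.fit_period_mixture(draws, 1)
        assert means[0] == pytest.approx(draws.mean(), abs=0.1)

    def test_unimodal_data_flags_overlap(self):
        rng = np.random.default_rng(19)
        draws = rng.normal(5.0, 1.0, 80)
        _, _, _, _, diag = pp.fit_period_mixture(draws, 2)
        assert diag["overlapping"]


class TestOutOfPlane:
    @pytest.fixture(scope="class")
    def space(self, small_disk_mesh):
        return StokesSystem(small_disk_mesh, 1.0).space

    def test_uniform_source_net_change(self, space):
        r0 = 0.05
        r = DivergenceSource(space, np.full(space.mesh.n_nodes, r0))
        v_out, v_in, net = pp.out_of_plane_volumes(r, DT)
        A = space.mesh.measure()
        assert net == pytest.approx(r0 * A * DT, rel=1e-12)
        assert v_out == 0.0
        assert v_in == pytest.approx(net, rel=1e-12)

    def test_balanced_source_sink(self, space):
        c = 0.03
        vals = np.where(space.mesh.nodes[:, 0] > 0.0, c, -c)
        r = DivergenceSource(space, vals)
        v_out, v_in, net = pp.out_of_plane_volumes(r, DT)
        assert v_in - v_out == pytest.approx(net, abs=1e-12 * (v_in + v_out))
        assert v_in > 0 and v_out > 0

    def test_3d_rejected(self):
        class Fake:
            dim = 3

        with pytest.raises(ValueError):
            pp.out_of_plane_volumes(DivergenceSource(space=Fake(),
                                                     dofs=np.zeros(1)), DT)


class TestAccelerationAndDarcy:
    def test_linear_ramp_constant_acceleration(self):
        speeds = 0.3 * np.arange(10) * DT
        acc = pp.bleb_acceleration(speeds, DT)
        np.testing.assert_allclose(acc, 0.3 * DT / DT, atol=1e-12)

    def test_constant_speed_zero_acceleration(self):
        np.testing.assert_allclose(pp.bleb_acceleration(np.full(8, 2.0), DT),
                                   0.0)

    def test_sinusoid_matches_derivative_to_first_order(self):
        t = np.arange(0, 20, DT)
        speed = np.sin(0.5 * t)
        acc = pp.bleb_acceleration(speed, DT)
        exact = 0.5 * np.cos(0.5 * (t[:-1] + DT / 2))
        assert np.abs(acc - exact).max() < 0.5 ** 3 * DT ** 2

    def test_darcy_cortex_estimate_in_reported_window(self):
        dp = pp.darcy_pressure(u=10.0, nu=1e-3, h=1.0, l=0.1)
        assert dp == pytest.approx(1.0)
        assert 0.99 <= dp <= 10.01  # the reported 1-10 Pa plausibility window

    @given(u=st.floats(0.1, 100), nu=st.floats(1e-4, 10),
           h=st.floats(0.1, 10), l=st.floats(0.01, 1))
    @settings(max_examples=30, deadline=None)
    def test_darcy_scalings(self, u, nu, h, l):
        base = pp.darcy_pressure(u, nu, h, l)
        assert pp.darcy_pressure(2 * u, nu, h, l) == pytest.approx(2 * base)
        assert pp.darcy_pressure(u, nu, h, l / 2) == pytest.approx(4 * base)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pp.darcy_pressure(0.0, 1e-3, 1.0, 0.1)
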
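import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibkit.params import INF, KineticParams, NoiseModel, QuenchParams, TitrationScheme
from inhibkit.simulate import (
    make_titration_concentrations,
    mixed_inhibition_rate,
    simulate_emission_spectrum,
    simulate_enzyme_series,
    simulate_progress_curve,
    simulate_rate_grid,
    simulate_titration,
)

from conftest import INHIBITOR_GRID, SUBSTRATE_GRID


class TestMixedInhibitionRate:
    def test_reduces_to_michaelis_menten_at_zero_inhibitor(self, kin_params):
        v = mixed_inhibition_rate(kin_params, s=25.0, i=0.0)
        assert v == pytest.approx(25.0 / 35.0, rel=1e-12)

    def test_hand_evaluated_mixed_velocity(self, kin_params):
        # denominator: 10*(1 + 10.6/10.6) + 25*(1 + 10.6/57.24)
        expected = 25.0 / (20.0 + 25.0 * (1.0 + 10.6 / 57.24))
        assert mixed_inhibition_rate(kin_params, 25.0, 10.6) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.50373, abs=5e-5)

    def test_saturation_limit_is_vmax(self, kin_params):
        assert mixed_inhibition_rate(kin_params, 1e12, 0.0) == pytest.approx(
            kin_params.vmax, rel=1e-9
        )

    def test_strictly_decreasing_in_inhibitor(self, kin_params):
        vs = [mixed_inhibition_rate(kin_params, 25.0, i) for i in (0, 1, 5, 20, 100)]
        assert all(b < a for a, b in zip(vs, vs[1:]))

    @pytest.mark.parametrize("s,i", [(0.0, 1.0), (-5.0, 1.0), (10.0, -0.1)])
    def test_domain_errors(self, kin_params, s, i):
        with pytest.raises(ValueError):
            mixed_inhibition_rate(kin_params, s, i)

    def test_infinite_sentinels_drop_terms(self):
        competitive = KineticParams(vmax=1, km=10, ki=5.0, kis=INF)
        v = mixed_inhibition_rate(competitive, 20.0, 10.0)
        assert v == pytest.approx(20.0 / (10.0 * 3.0 + 20.0), rel=1e-12)
        uncompetitive = KineticParams(vmax=1, km=10, ki=INF, kis=5.0)
        v = mixed_inhibition_rate(uncompetitive, 20.0, 10.0)
        assert v == pytest.approx(20.0 / (10.0 + 20.0 * 3.0), rel=1e-12)


class TestProgressCurve:
    def test_affine_construction(self, noiseless):
        # velocity 0.5 from Vmax=1, Km=25 at S=25
        p = KineticParams(vmax=1.0, km=25.0, ki=10.0, kis=10.0)
        c = simulate_progress_curve(
            p, s=25.0, i=0.0, e_scale=1.0, times=[0, 60, 120], noise=noiseless,
            k=1.0, od_bg=0.05,
        )
        np.testing.assert_allclose(c.od, [0.05, 30.05, 60.05], rtol=1e-12)

    def test_seed_determinism(self, kin_params):
        noise = NoiseModel(rel_sd=0.05, seed=42)
        t = np.arange(0, 600, 60)
        a = simulate_progress_curve(kin_params, 25, 5.21, 1.0, t, noise)
        b = simulate_progress_curve(kin_params, 25, 5.21, 1.0, t, noise)
        np.testing.assert_array_equal(a.od, b.od)

    def test_doubling_enzyme_doubles_slope(self, kin_params, noiseless):
        t = np.arange(0, 300, 60)
        c1 = simulate_progress_curve(kin_params, 25, 0, 1.0, t, noiseless, od_bg=0)
        c2 = simulate_progress_curve(kin_params, 25, 0, 2.0, t, noiseless, od_bg=0)
        slope1 = (c1.od[-1] - c1.od[0]) / (c1.t[-1] - c1.t[0])
        slope2 = (c2.od[-1] - c2.od[0]) / (c2.t[-1] - c2.t[0])
        assert slope2 == pytest.approx(2.0 * slope1, rel=1e-12)

    def test_empty_times_rejected(self, kin_params, noiseless):
        with pytest.raises(ValueError):
            simulate_progress_curve(kin_params, 25, 0, 1.0, [], noiseless)


class TestRateGrid:
    def test_default_grid_row_count(self, kin_params, noiseless):
        table = simulate_rate_grid(kin_params, noise=noiseless)
        assert len(table) == len(SUBSTRATE_GRID) * len(INHIBITOR_GRID) == 20

    def test_noiseless_matches_rate_law(self, kin_params, noiseless):
        table = simulate_rate_grid(kin_params, noise=noiseless)
        for s, i, v in zip(table.substrate_uM, table.inhibitor_uM, table.velocity):
            assert v == mixed_inhibition_rate(kin_params, s, i)

    def test_velocity_monotone_in_inhibitor(self, kin_params, noiseless):
        table = simulate_rate_grid(kin_params, noise=noiseless).to_frame()
        for s, grp in table.groupby("substrate_uM"):
            grp = grp.sort_values("inhibitor_uM")
            assert grp["velocity"].is_monotonic_decreasing

    def test_duplicate_pairs_rejected(self, kin_params, noiseless):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_rate_grid(kin_params, [25.0, 25.0], [0.0], noiseless)


class TestEnzymeSeries:
    def test_velocities_linear_in_enzyme(self, kin_params, noiseless):
        table = simulate_enzyme_series(
            kin_params, 100.0, [0.0], [0.5, 1.0, 2.0], noiseless
        )
        v = table.velocity
        np.testing.assert_allclose(v / v[1], [0.5, 1.0, 2.0], rtol=1e-12)

    def test_noiseless_lines_pass_origin(self, kin_params, noiseless):
        from conftest import ols_slope_intercept

        table = simulate_enzyme_series(
            kin_params, 100.0, [0.0, 41.67], [0.5, 1.0, 1.5, 2.0], noiseless
        ).to_frame()
        for _, grp in table.groupby("inhibitor_uM"):
            _, intercept = ols_slope_intercept(
                grp["enzyme_scale"], grp["velocity"]
            )
            assert abs(intercept) < 1e-14

    def test_slope_falls_with_inhibitor(self, kin_params, noiseless):
        from conftest import ols_slope_intercept

        table = simulate_enzyme_series(
            kin_params, 100.0, [0.0, 41.67], [0.5, 1.0, 2.0], noiseless
        ).to_frame()
        slopes = {
            i: ols_slope_intercept(g["enzyme_scale"], g["velocity"])[0]
            for i, g in table.groupby("inhibitor_uM")
        }
        assert slopes[41.67] < slopes[0.0]

    def test_single_enzyme_level_rejected(self, kin_params, noiseless):
        with pytest.raises(ValueError):
            simulate_enzyme_series(kin_params, 100.0, [0.0], [1.0], noiseless)


class TestTitrationScheme:
    # concentrations printed in the published titration legend
    PRINTED = [0.0, 4.76, 9.09, 13.04, 16.67, 20.00, 23.08, 25.92, 28.57]

    def test_reproduces_printed_concentrations(self, scheme):
        conc = make_titration_concentrations(scheme)
        np.testing.assert_allclose(conc, self.PRINTED, atol=0.01)

    def test_no_additions(self):
        s = TitrationScheme(n_additions=0)
        np.testing.assert_array_equal(make_titration_concentrations(s), [0.0])

    def test_strictly_increasing(self, scheme):
        assert np.all(np.diff(make_titration_concentrations(scheme)) > 0)


class TestSimulateTitration:
    def test_stern_volmer_law_holds(self, quench_params_298, scheme, noiseless):
        s = simulate_titration(quench_params_298, scheme, 298.0, "stern_volmer",
                               noiseless)
        fc = s.f_measured * np.exp((s.a_ex + s.a_em) / 2.0)
        f0 = fc[0]
        # last point: [Q] = 28.571 μmol/L -> F/F0 = 1/(1 + Ksv*[Q])
        expected = 1.0 / (1.0 + 1.881e5 * (80.0 / 2.8) * 1e-6)
        assert fc[-1] / f0 == pytest.approx(expected, rel=1e-9)
        assert fc[-1] / f0 == pytest.approx(0.15688, abs=5e-5)

    def test_double_log_law_holds(self, scheme, noiseless):
        q = QuenchParams(f0=500.0, ksv=1e5, ka=1.67e4, n=1.183)
        s = simulate_titration(q, scheme, 298.0, "double_log", noiseless)
        # no inner filter (eps=0): Fm == Fc
        np.testing.assert_array_equal(s.a_ex, 0.0)
        f = s.f_measured
        ratio = (f[0] - f) / f
        conc_m = s.quencher_uM * 1e-6
        np.testing.assert_allclose(ratio[1:], 1.67e4 * conc_m[1:] ** 1.183,
                                   rtol=1e-10)
        # hand value at [Q]=1e-5 mol/L
        assert 1.67e4 * (1e-5) ** 1.183 == pytest.approx(0.02032, abs=5e-5)

    def test_no_inner_filter_means_identity(self, scheme, noiseless):
        q = QuenchParams(f0=1000.0, ksv=1e5, ka=1e4, n=1.0, eps_ex=0.0, eps_em=0.0)
        s = simulate_titration(q, scheme, 298.0, "stern_volmer", noiseless)
        fc = s.f_measured * np.exp((s.a_ex + s.a_em) / 2.0)
        np.testing.assert_array_equal(fc, s.f_measured)

    def test_unknown_mode_rejected(self, quench_params_298, scheme, noiseless):
        with pytest.raises(ValueError, match="mode"):
            simulate_titration(quench_params_298, scheme, 298.0, "bogus", noiseless)

    def test_determinism(self, quench_params_298, scheme):
        noise = NoiseModel(rel_sd=0.02, seed=7)
        a = simulate_titration(quench_params_298, scheme, 298.0, "stern_volmer", noise)
        b = simulate_titration(quench_params_298, scheme, 298.0, "stern_volmer", noise)
        np.testing.assert_array_equal(a.f_measured, b.f_measured)


class TestNoiseModel:
    def test_noise_scaling(self):
        # empirical relative SD matches rel_sd within 3/sqrt(N)
        rel_sd = 0.02
        n = 20000
        noise = NoiseModel(rel_sd=rel_sd, seed=123)
        signal = np.full(n, 10.0)
        noisy = noise.apply(signal)
        resid = noisy / signal - 1.0
        assert np.std(resid) == pytest.approx(rel_sd, rel=3.0 / np.sqrt(n))

    def test_zero_noise_is_exact_copy(self):
        noise = NoiseModel(rel_sd=0.0, seed=5)
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(noise.apply(x), x)

    def test_negative_rel_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(rel_sd=-0.01, seed=0)


class TestEmissionSpectrum:
    def test_two_gaussian_peaks(self, noiseless):
        wl, inten = simulate_emission_spectrum(noise=noiseless)
        from inhibkit.fluorescence import emission_peak

        result = emission_peak(wl, inten)
        assert len(result.peaks_nm) == 2
        assert result.peaks_nm[0] == pytest.approx(336.0, abs=0.5)
        assert result.peaks_nm[1] == pytest.approx(404.0, abs=0.5)


@given(
    vmax=st.floats(0.1, 10.0),
    km=st.floats(1.0, 100.0),
    ki=st.floats(1.0, 100.0),
    kis=st.floats(1.0, 100.0),
    s=st.floats(1.0, 100.0),
    i=st.floats(0.0, 100.0),
)
@settings(max_examples=200, deadline=None)
def test_rate_positive_and_bounded_by_vmax(vmax, km, ki, kis, s, i):
    p = KineticParams(vmax=vmax, km=km, ki=ki, kis=kis)
    v = mixed_inhibition_rate(p, s, i)
    assert 0 < v < vmax
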
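"""Derived observables: dose-response, Km, cooperativity, threshold, ratios."""

import numpy as np
import pytest

from pghs1net import SimulationConfig, simulate
from pghs1net.observables import (
    DoseResponseCurve,
    activation_threshold,
    activity_duration,
    apparent_km,
    auc,
    consumption_ratio,
    dose_response,
    eadie_scatchard,
    flux_table,
    oxygen_consumption_rate,
)

AA_GRID = (0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0)


def michaelis_curve(vmax=10.0, km=3.0, grid=None):
    grid = np.asarray(grid if grid is not None else np.geomspace(0.05, 3000, 40))
    return DoseResponseCurve(
        aa_grid=grid,
        rates=vmax * grid / (km + grid),
        rc=0.0,
        config=SimulationConfig(enzyme_total=0.035, t_end=60.0),
    )


@pytest.fixture(scope="module")
def dose_curves(model):
    cfg = SimulationConfig(enzyme_total=0.035, t_end=120.0)
    return {
        rc: dose_response(model, AA_GRID, rc, cfg) for rc in (10.0, 1000.0, 5000.0)
    }


class TestOxygenConsumption:
    def test_zero_enzyme_gives_zero_rate(self, model):
        traj = simulate(model, SimulationConfig(enzyme_total=0.0, aa0=80.0,
                                                rc0=100.0, t_end=30.0))
        assert np.all(oxygen_consumption_rate(traj) == 0.0)

    def test_single_burst_shape(self, model):
        """The rate rises to one maximum and decays as the enzyme dies."""
        traj = simulate(model, SimulationConfig(enzyme_total=0.035, aa0=80.0,
                                                rc0=300.0, t_end=300.0))
        v = oxygen_consumption_rate(traj)
        peak = int(np.argmax(v))
        assert 0 < peak < len(v) - 1
        assert v[-1] < 0.05 * v[peak]
        # decays monotonically (to grid resolution) well after the peak
        tail = v[np.searchsorted(traj.t, 2 * traj.t[peak]):]
        assert np.all(np.diff(tail) < 1e-4)

    def test_integral_equals_o2_consumed(self, long_traj):
        consumed = long_traj.config.o2_0 - long_traj.conc("O2")[-1]
        total = auc(oxygen_consumption_rate(long_traj), long_traj.t)
        assert total == pytest.approx(consumed, rel=1e-3)


class TestAuc:
    def test_constant_series(self):
        t = np.linspace(0.0, 7.0, 29)
        assert auc(np.full_like(t, 3.0), t) == pytest.approx(21.0)

    def test_grid_refinement_invariance(self, model):
        cfg = SimulationConfig(enzyme_total=0.035, aa0=80.0, rc0=100.0,
                               t_end=300.0, n_points=800)
        fine = SimulationConfig(enzyme_total=0.035, aa0=80.0, rc0=100.0,
                                t_end=300.0, n_points=1600)
        a = simulate(model, cfg)
        b = simulate(model, fine)
        ra = auc(a.conc("PGH2"), a.t)
        rb = auc(b.conc("PGH2"), b.t)
        assert abs(ra - rb) / rb < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(3), np.linspace(0, 1, 4))


class TestDoseResponse:
    def test_zero_aa_gives_zero_rate(self, model):
        cfg = SimulationConfig(enzyme_total=0.035, t_end=60.0)
        curve = dose_response(model, [0.0, 1.0], 100.0, cfg)
        assert curve.rates[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_non_decreasing_at_high_rc(self, dose_curves):
        assert np.all(np.diff(dose_curves[1000.0].rates) >= -1e-9)

    def test_rc_inhibits_and_right_shifts_the_curve(self, dose_curves):
        low, high = dose_curves[10.0], dose_curves[5000.0]
        assert high.rates.max() < low.rates.max()
        km_low, _ = apparent_km(low)
        km_high, _ = apparent_km(high)
        assert km_high > km_low

    def test_km_increases_with_rc(self, dose_curves):
        kms = [apparent_km(dose_curves[rc])[0] for rc in (10.0, 1000.0, 5000.0)]
        assert kms[0] < kms[1] < kms[2]

    def test_default_km_is_in_the_experimental_window(self, dose_curves):
        # apparent Km for AA of order 1-10 uM at high cosubstrate
        km, _ = apparent_km(dose_curves[1000.0])
        assert 0.5 < km < 10.0


class TestApparentKm:
    def test_exact_michaelis_closed_form(self):
        km, vmax = apparent_km(michaelis_curve())
        assert vmax == pytest.approx(10.0, rel=0.01)
        assert km == pytest.approx(3.0, rel=0.02)

    def test_no_plateau_is_flagged(self):
        curve = michaelis_curve(grid=np.linspace(0.1, 2.0, 10))  # far below Km
        with pytest.raises(ValueError, match="plateau"):
            apparent_km(curve)


class TestEadieScatchard:
    def test_michaelis_points_fall_on_a_line_with_slope_minus_one_over_km(self):
        curve = michaelis_curve(vmax=10.0, km=3.0)
        e = 0.035
        x, y, concavity = eadie_scatchard(curve, e)
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(-1.0 / 3.0, rel=1e-6)
        assert abs(concavity) < 1e-9

    def test_model_is_downward_concave_at_high_rc(self, dose_curves):
        _x, _y, concavity = eadie_scatchard(dose_curves[1000.0], 0.035)
        assert concavity < 0.0  # positive-cooperativity signature

    def test_concavity_sign_separates_michaelis_from_the_model(self, dose_curves):
        _x, _y, c_toy = eadie_scatchard(michaelis_curve(), 0.035)
        _x, _y, c_model = eadie_scatchard(dose_curves[1000.0], 0.035)
        assert c_model < c_toy - 1e-3


class TestActivationThreshold:
    def test_zero_criterion_returns_lower_bound(self, model):
        curve = activation_threshold(model, [100.0], criterion=0.0, t_eval=30.0)
        assert curve.threshold_aa[0] == pytest.approx(1e-3)

    def test_threshold_increases_with_rc(self, model):
        cfg = SimulationConfig(enzyme_total=0.035, t_end=300.0, n_points=200)
        curve = activation_threshold(
            model, [10.0, 100.0, 1000.0], criterion=0.02, t_eval=300.0, config=cfg
        )
        aa = curve.threshold_aa
        assert not curve.flags
        assert aa[0] < aa[1] < aa[2]
        assert np.all(aa > 0)

    def test_result_independent_of_starting_bracket(self, model):
        cfg = SimulationConfig(enzyme_total=0.035, t_end=300.0, n_points=200)
        a = activation_threshold(model, [100.0], config=cfg,
                                 aa_bracket=(1e-3, 50.0)).threshold_aa[0]
        b = activation_threshold(model, [100.0], config=cfg,
                                 aa_bracket=(3e-3, 10.0)).threshold_aa[0]
        assert abs(a - b) / b < 0.02


class TestConsumptionRatio:
    def test_no_rc_oxidation_gives_zero_ratio(self, model):
        m = model.with_params(
            model.params.with_values(k5=0.0, k6=0.0, k8=0.0, k10=0.0)
        )
        traj = simulate(m, SimulationConfig(enzyme_total=0.035, aa0=40.0,
                                            rc0=40.0, t_end=60.0))
        assert consumption_ratio(traj, 30.0) == pytest.approx(0.0, abs=1e-9)

    def test_saturating_dependence_on_initial_ratio(self, model):
        """Non-decreasing in RC0/AA0 and flattening, not linear."""
        ratios = []
        for rc0 in (20.0, 50.0, 100.0):
            traj = simulate(model, SimulationConfig(enzyme_total=0.035, aa0=40.0,
                                                    rc0=rc0, t_end=60.0))
            ratios.append(consumption_ratio(traj, 30.0))
        assert ratios[0] < ratios[1] < ratios[2]
        gain1 = (ratios[1] - ratios[0]) / (50.0 - 20.0)
        gain2 = (ratios[2] - ratios[1]) / (100.0 - 50.0)
        assert gain2 < gain1  # saturation

    def test_bounded_by_two_rc_per_conversion(self, model):
        for aa0, rc0 in ((20.0, 100.0), (80.0, 50.0)):
            traj = simulate(model, SimulationConfig(enzyme_total=0.035, aa0=aa0,
                                                    rc0=rc0, t_end=60.0))
            r = consumption_ratio(traj, 30.0)
            assert 0.0 < r <= 2.0

    def test_time_outside_span_rejected(self, model):
        traj = simulate(model, SimulationConfig(enzyme_total=0.035, aa0=40.0,
                                                rc0=40.0, t_end=10.0))
        with pytest.raises(ValueError):
            consumption_ratio(traj, 30.0)


class TestFluxTable:
    def test_inactivation_free_maxima_dominate_default_maxima(self, model):
        free = model.with_params(
            model.params.with_values(kin=0.0, kin1=0.0, kin2=0.0)
        )
        base = flux_table(model, [100.0])
        upper = flux_table(free, [100.0])
        assert (upper.loc[100.0] >= base.loc[100.0] - 1e-12).all()

    def test_rejects_non_positive_rc(self, model):
        with pytest.raises(ValueError):
            flux_table(model, [0.0])


class TestActivityDuration:
    def test_zero_enzyme_has_zero_duration(self, model):
        traj = simulate(model, SimulationConfig(enzyme_total=0.0, aa0=80.0,
                                                rc0=300.0, t_end=60.0))
        assert activity_duration(traj) == 0.0

    def test_high_rc_shortens_nothing_but_bounds_hold(self, flux_analysis_traj):
        d = activity_duration(flux_analysis_traj)
        assert 0.0 < d < flux_analysis_traj.t[-1]
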
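"""Stress-strain derivation: zeroing, landmarks, energies, aggregation."""

import numpy as np
import pytest

from tendonmech import mechanics as mech
from tendonmech.errors import (
    ConfigurationError,
    ContractError,
    DegenerateTraceError,
    NumericError,
    PipelineError,
)
from tendonmech.io import LoadDisplacementTrace
from tendonmech.simulate import TraceParams, simulate_trace


def make_trace(disp_mm, load_g, specimen_id="t"):
    n = len(disp_mm)
    return LoadDisplacementTrace(
        specimen_id=specimen_id, time_ms=np.arange(n, dtype=float),
        disp_signal_mv=np.zeros(n), load_signal_mv=np.zeros(n),
        disp_mm=np.asarray(disp_mm, float), load_g=np.asarray(load_g, float))


def make_curve(strain, stress, L0=5.0, A=0.07):
    return mech.StressStrainCurve(strain=np.asarray(strain, float),
                                  stress=np.asarray(stress, float),
                                  L0=L0, A=A)


CFG = dict(diameter=0.3, laststrainpt=0.14)


class TestZeroTrace:
    def test_cutoff_scan_matches_linear_scan_oracle(self):
        loads = [0.1, 0.4, 1.0, 40.0, 100.0]
        disp = [0.0, 1.0, 2.0, 3.0, 4.0]
        cutoff = 0.01 * max(loads)
        oracle = next(i for i, v in enumerate(loads) if v >= cutoff)
        z = mech.zero_trace(make_trace(disp, loads),
                            mech.AnalysisConfig(**CFG))
        assert oracle == 2
        assert z.L0 == 2.0
        assert z.disp_mm.tolist() == [0.0, 1.0, 2.0]
        assert z.load_g[0] == 0.0

    def test_first_sample_above_cutoff_keeps_series(self):
        z = mech.zero_trace(make_trace([1.0, 2.0, 3.0], [5.0, 6.0, 9.0]),
                            mech.AnalysisConfig(**CFG))
        assert z.L0 == 1.0
        assert len(z.disp_mm) == 3
        assert z.load_g.tolist() == [0.0, 1.0, 4.0]

    def test_all_zero_load_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            mech.zero_trace(make_trace([0.0, 1.0], [0.0, 0.0]),
                            mech.AnalysisConfig(**CFG))

    def test_manual_truncation_mode(self):
        cfg = mech.AnalysisConfig(**CFG, loadat1percent=False,
                                  manual_start_index=1)
        z = mech.zero_trace(make_trace([1.0, 2.0, 3.0], [0.0, 1.0, 9.0]),
                            cfg)
        assert z.L0 == 2.0 and len(z.disp_mm) == 2

    def test_manual_mode_requires_index(self):
        with pytest.raises(ConfigurationError):
            mech.AnalysisConfig(**CFG, loadat1percent=False)


class TestToStressStrain:
    def test_area_from_thickness(self):
        # d = 0.1 mm -> A = pi d^2/4 = 8e-3 mm^2 to 1 significant figure
        g = mech.FascicleGeometry(d=0.1)
        assert g.A == pytest.approx(np.pi * 0.01 / 4)
        assert float(f"{g.A:.0e}") == 8e-3

    def test_strain_is_displacement_over_gauge_length(self):
        z = mech.ZeroedTrace(disp_mm=np.array([0.0, 1.0]),
                             load_g=np.array([0.0, 10.0]), L0=5.0)
        curve = mech.to_stress_strain(z, None, mech.AnalysisConfig(**CFG))
        assert curve.strain[-1] == pytest.approx(0.2)

    def test_zero_load_gives_zero_stress_at_origin(self):
        z = mech.ZeroedTrace(disp_mm=np.array([0.0, 1.0]),
                             load_g=np.array([0.0, 10.0]), L0=5.0)
        curve = mech.to_stress_strain(z, None, mech.AnalysisConfig(**CFG))
        assert curve.stress[0] == 0.0
        # sigma = P g0 / A in MPa
        A = np.pi * 0.3 ** 2 / 4
        assert curve.stress[-1] == pytest.approx(10 * 9.80665e-3 / A)


class TestLocateYield:
    def test_logistic_fixture_detects_the_max_slope_grid_point(self):
        """Yield index is adjacent to the grid point nearest the analytic
        max-slope location of a sharp logistic."""
        eps = np.linspace(0.0, 0.12, 500)
        sig = 50.0 / (1.0 + np.exp(-100.0 * (eps - 0.05)))
        curve = make_curve(eps, sig - sig[0])
        res = mech.locate_yield(curve, orderpoly=5)
        nearest = int(np.argmin(np.abs(eps - 0.05)))
        assert abs(res.p - nearest) <= 1

    def test_exactly_linear_curve(self):
        eps = np.linspace(0.0, 0.1, 60)
        curve = make_curve(eps, 600.0 * eps)
        res = mech.locate_yield(curve, orderpoly=3)
        assert res.p == 0  # constant gradient: tie broken to earliest index
        assert res.E == pytest.approx(600.0, rel=1e-6)
        assert res.boundary_warning

    def test_too_few_points_is_numeric_error(self):
        eps = np.linspace(0.0, 0.1, 5)
        curve = make_curve(eps, 600.0 * eps)
        with pytest.raises(NumericError):
            mech.locate_yield(curve, orderpoly=5)

    @pytest.mark.parametrize("n", [200, 500, 1200])
    def test_location_converges_with_grid_density(self, n):
        """On a smooth monotone curve the detected yield strain approaches
        the analytic max-slope point as the grid refines."""
        eps = np.linspace(0.0, 0.12, n)
        sig = 30.0 / (1.0 + np.exp(-50.0 * (eps - 0.06)))
        curve = make_curve(eps, sig - sig[0])
        res = mech.locate_yield(curve, orderpoly=5)
        assert abs(res.eps_Y - 0.06) <= max(2 * 0.12 / (n - 1), 2e-3)


class TestLocateRupture:
    def _curve(self):
        eps = np.linspace(0.0, 0.15, 151)
        stress = np.concatenate([np.linspace(0, 30, 100),
                                 np.linspace(30, 10, 51)[1:]])
        return make_curve(eps, stress)

    def test_scan_matches_oracle(self):
        curve = self._curve()
        r, warn = mech.locate_rupture(curve, laststrainpt=0.12)
        oracle = max(i for i, e in enumerate(curve.strain) if e <= 0.12)
        assert (r, warn) == (oracle, False)

    def test_estimate_beyond_record_falls_back_to_final_sample(self):
        curve = self._curve()
        r, warn = mech.locate_rupture(curve, laststrainpt=0.5)
        assert (r, warn) == (len(curve.strain) - 1, False)

    def test_estimate_below_max_stress_warns_and_uses_final_sample(self):
        curve = self._curve()
        r, warn = mech.locate_rupture(curve, laststrainpt=0.01)
        assert (r, warn) == (len(curve.strain) - 1, True)


class TestStrainEnergy:
    def test_linear_ramp_closed_form(self):
        eps = np.linspace(0.0, 0.1, 11)
        curve = make_curve(eps, 100.0 * eps)  # sigma_Y = 10 at eps_Y = 0.1
        u_Y, u_P, u_R, u_F, u_0 = mech.strain_energy_partition(
            curve, p=10, q=10, r=10)
        assert u_Y == pytest.approx(0.5)      # 1/2 sigma_Y eps_Y
        assert u_P == u_R == 0.0 and u_0 == u_Y

    def test_quadratic_against_analytic_integral(self):
        eps = np.linspace(0.0, 0.1, 1000)
        curve = make_curve(eps, 100.0 * eps ** 2)
        *_, u_0 = mech.strain_energy_partition(curve, p=400, q=700, r=999)
        assert u_0 == pytest.approx(100 * 0.1 ** 3 / 3, rel=1e-5)

    def test_degenerate_partition(self):
        eps = np.linspace(0.0, 0.1, 50)
        curve = make_curve(eps, 200.0 * eps)
        u_Y, u_P, u_R, u_F, u_0 = mech.strain_energy_partition(
            curve, p=49, q=49, r=49)
        assert u_P == 0.0 and u_R == 0.0 and u_0 == u_Y

    def test_partition_identity_is_exact(self, rng):
        eps = np.sort(rng.random(300)) * 0.1
        eps[0] = 0.0
        sig = np.abs(rng.normal(10, 3, 300))
        sig[0] = 0.0
        curve = make_curve(eps, sig)
        u_Y, u_P, u_R, u_F, u_0 = mech.strain_energy_partition(
            curve, p=100, q=200, r=299)
        assert u_F == u_P + u_R                # shared endpoints: exact
        assert u_0 == u_Y + u_F


class TestDeriveProperties:
    def test_recovery_from_ground_truth(self, default_trace, default_cfg):
        trace, truth = default_trace
        props, curve = mech.derive_properties(trace, default_cfg)
        assert props.E == pytest.approx(truth.E, rel=0.05)
        assert props.sigma_U == pytest.approx(truth.sigma_U, rel=0.05)
        assert props.u_0 == pytest.approx(truth.u_0, rel=0.10)
        assert props.u_F == props.u_P + props.u_R
        assert props.u_0 == props.u_Y + props.u_F
        assert props.E >= props.sigma_U / props.eps_U
        assert props.eps_Y <= props.eps_U
        assert curve.O <= curve.p <= curve.q <= curve.r

    def test_zero_noise_recovery_is_tight(self, default_cfg):
        trace, truth = simulate_trace(TraceParams(noise_sd_g=0.0, seed=0))
        props, _ = mech.derive_properties(trace, default_cfg)
        assert props.sigma_U == pytest.approx(truth.sigma_U, rel=0.02)

    def test_stage_tagging_on_zeroing_failure(self, default_cfg):
        n = 10
        trace = LoadDisplacementTrace(
            "t", np.arange(n, dtype=float), np.zeros(n), np.zeros(n),
            np.linspace(0, 1, n), np.zeros(n))
        with pytest.raises(PipelineError) as ei:
            mech.derive_properties(trace, default_cfg)
        assert ei.value.stage == "zero_trace"


class TestAggregate:
    def test_two_tails_mean_and_sem(self):
        import pandas as pd
        df = pd.DataFrame({"age_group": ["01M", "01M"], "sample": ["1", "2"],
                           "E": [10.0, 20.0]})
        tails, groups = mech.aggregate(df)
        assert groups.loc[0, "mean_E"] == 15.0
        assert groups.loc[0, "sem_E"] == pytest.approx(5.0)  # SD/sqrt(2)

    def test_single_tail_reports_missing_sem(self):
        import pandas as pd
        df = pd.DataFrame({"age_group": ["01M"], "sample": ["1"],
                           "E": [10.0]})
        _, groups = mech.aggregate(df)
        assert groups.loc[0, "mean_E"] == 10.0
        assert np.isnan(groups.loc[0, "sem_E"])

    def test_matches_nested_loop_oracle(self, rng):
        import pandas as pd
        rows = []
        for g in ("01M", "11M"):
            for tail in range(3):
                for spec in range(rng.integers(1, 5)):
                    rows.append({"age_group": g, "sample": str(tail),
                                 "E": float(rng.normal(500, 60))})
        df = pd.DataFrame(rows)
        _, groups = mech.aggregate(df)
        for g in ("01M", "11M"):
            tail_means = [np.mean([r["E"] for r in rows
                                   if r["age_group"] == g
                                   and r["sample"] == str(t)])
                          for t in range(3)]
            assert groups.set_index("age_group").loc[g, "mean_E"] == (
                pytest.approx(np.mean(tail_means)))
            assert groups.set_index("age_group").loc[g, "sem_E"] == (
                pytest.approx(np.std(tail_means, ddof=1) / np.sqrt(3)))

    def test_empty_input_is_contract_error(self):
        import pandas as pd
        with pytest.raises(ContractError):
            mech.aggregate(pd.DataFrame(columns=["age_group", "sample"]))
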
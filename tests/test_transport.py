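"""Transport solver: inputs, diffusion scaling, closed-form oracles,
conservation, convergence."""

import numpy as np
import pytest
import scipy.stats as st

from ctbolus.pbpk import (IOPAMIDOL_370, SIMULATION_AGENT_350, ContrastAgent,
                          InjectionProtocol, PatientModel,
                          representative_subject,
                          test_bolus_protocol as timing_bolus)
from ctbolus.transport import (SolverSettings, SolverError, TimeDensityCurve,
                               TransportState, carrier_flow, derivatives,
                               diffusion_coefficient, injection_input,
                               simulate, simulate_cohort, to_hounsfield)


class TestInjectionInput:
    def test_rate_during_injection(self):
        proto = InjectionProtocol(cm_volume=45.5, agent=SIMULATION_AGENT_350,
                                  injection_duration=10.0)
        assert injection_input(proto, 4.0) == pytest.approx(
            (45.5 / 10.0) * 350.0)

    def test_zero_after_flush(self):
        proto = timing_bolus()
        t_end = proto.injection_duration + proto.flush_duration
        assert injection_input(proto, t_end + 0.1) == 0.0
        assert carrier_flow(proto, t_end + 0.1) == 0.0

    def test_flush_carries_flow_but_no_iodine(self):
        proto = timing_bolus()
        t = proto.injection_duration + 0.5
        assert injection_input(proto, t) == 0.0
        assert carrier_flow(proto, t) == proto.flush_rate

    def test_mass_integral_equals_dose(self):
        proto = timing_bolus()
        t = np.linspace(0, 30, 30001)
        rate = np.array([injection_input(proto, x) for x in t])
        total = np.trapezoid(rate, t)
        assert total == pytest.approx(proto.total_iodine, rel=1e-3)


class TestDiffusionCoefficient:
    def test_reference_identity(self):
        k = diffusion_coefficient(IOPAMIDOL_370, IOPAMIDOL_370, 0.15)
        assert k == 0.15

    def test_osmotic_proportionality(self):
        doubled = ContrastAgent("2x", 370, 9.1,
                                osmotic_ratio=2 * IOPAMIDOL_370.osmotic_ratio)
        assert diffusion_coefficient(doubled, IOPAMIDOL_370, 0.15) == \
            pytest.approx(0.30)

    def test_simulation_agent_value(self):
        # osmolality 590 vs saline 290, against the reference ratio 2.76
        k = diffusion_coefficient(SIMULATION_AGENT_350, IOPAMIDOL_370, 0.15)
        assert k == pytest.approx(0.15 * (590 / 290) / 2.76, rel=1e-12)

    def test_viscosity_mode(self):
        thin = ContrastAgent("thin", 300, 4.55, osmotic_ratio=2.76)
        k = diffusion_coefficient(thin, IOPAMIDOL_370, 0.15,
                                  mode="osmotic_viscosity")
        assert k == pytest.approx(0.15 * (9.1 / 4.55), rel=1e-12)


class TestDerivatives:
    def test_zero_state_zero_input_gives_zero(self, tank_loop,
                                              zero_volume_protocol):
        net = tank_loop(600.0, 50.0, 3)
        state = TransportState(masses={"tank": np.zeros(3),
                                       "buffer": np.zeros(1)},
                               extracellular={}, time=50.0)
        d = derivatives(state, net, zero_volume_protocol, SolverSettings())
        assert all(np.all(v == 0) for v in d.masses.values())

    def test_negative_mass_rejected(self, tank_loop, zero_volume_protocol):
        net = tank_loop(600.0, 50.0, 3)
        state = TransportState(masses={"tank": np.array([-1.0, 0, 0]),
                                       "buffer": np.zeros(1)},
                               extracellular={})
        with pytest.raises(SolverError):
            derivatives(state, net, zero_volume_protocol, SolverSettings())


class TestClosedFormOracles:
    def test_single_tank_exponential_washout(self, tank_loop,
                                             zero_volume_protocol):
        # K=1, no diffusion/exchange: well-mixed compartment, m(t) =
        # m0 exp(-Q t / V)
        q_ml_min, v = 600.0, 50.0
        net = tank_loop(q_ml_min, v, 1)
        m0 = 100.0
        init = TransportState(masses={"tank": np.array([m0]),
                                      "buffer": np.zeros(1)},
                              extracellular={})
        s = SolverSettings(dt=0.05, horizon=10.0, k_ref=0.0)
        curve = simulate(None, zero_volume_protocol, ["tank"], s,
                         network=net, initial_state=init)["tank"]
        expected = m0 * np.exp(-(q_ml_min / 60.0) * curve.time / v) / v
        mask = expected > 1e-6
        rel = np.abs(curve.iodine_concentration[mask] - expected[mask]) \
            / expected[mask]
        assert rel.max() < 1e-3

    @pytest.mark.parametrize("n_sub", [3, 15])
    def test_tanks_in_series_erlang_impulse(self, tank_loop,
                                            zero_volume_protocol, n_sub):
        # outlet concentration after an impulse equals m0 * Erlang(K,
        # K Q / V) / Q
        q_ml_min, v, m0 = 600.0, 50.0, 100.0
        q = q_ml_min / 60.0
        net = tank_loop(q_ml_min, v, n_sub)
        masses = np.zeros(n_sub)
        masses[0] = m0
        init = TransportState(masses={"tank": masses, "buffer": np.zeros(1)},
                              extracellular={})
        s = SolverSettings(dt=0.01, horizon=25.0, k_ref=0.0,
                           readout="outlet")
        curve = simulate(None, zero_volume_protocol, ["tank"], s,
                         network=net, initial_state=init)["tank"]
        rate = n_sub * q / v
        expected = m0 * st.gamma.pdf(curve.time, a=n_sub,
                                     scale=1.0 / rate) / q
        l1 = np.trapezoid(np.abs(curve.iodine_concentration - expected),
                          curve.time)
        norm = np.trapezoid(expected, curve.time)
        assert l1 / norm < 0.01


class TestWholeBodySimulation:
    @pytest.fixture(scope="class")
    def coronary_run(self):
        patient = representative_subject(2.5)
        proto = InjectionProtocol(cm_volume=45.5, agent=SIMULATION_AGENT_350,
                                  injection_duration=10.0, flush_volume=20.0)
        s = SolverSettings(horizon=90.0)
        curves, diag = simulate(patient, proto, ["ascending_aorta",
                                                 "abdominal_aorta"],
                                s, return_diagnostics=True)
        return proto, curves, diag

    def test_mass_conserved_at_every_step(self, coronary_run):
        proto, _, diag = coronary_run
        scale = max(proto.total_iodine, 1.0)
        err = np.abs(diag.total_mass - diag.injected_mass) / scale
        assert err.max() <= 1e-6

    def test_all_mass_injected(self, coronary_run):
        proto, _, diag = coronary_run
        assert diag.injected_mass[-1] == pytest.approx(proto.total_iodine)

    def test_concentrations_non_negative(self, coronary_run):
        _, curves, _ = coronary_run
        for c in curves.values():
            assert c.iodine_concentration.min() >= -1e-9

    def test_abdominal_lags_ascending(self, coronary_run):
        _, curves, _ = coronary_run
        t_asc = curves["ascending_aorta"].time[
            np.argmax(curves["ascending_aorta"].enhancement)]
        t_abd = curves["abdominal_aorta"].time[
            np.argmax(curves["abdominal_aorta"].enhancement)]
        assert t_abd > t_asc

    def test_zero_volume_gives_flat_curves(self):
        patient = representative_subject(2.5)
        proto = InjectionProtocol(cm_volume=0.0, agent=SIMULATION_AGENT_350,
                                  injection_rate=4.0)
        s = SolverSettings(horizon=20.0)
        curves = simulate(patient, proto, ["ascending_aorta"], s)
        assert np.all(curves["ascending_aorta"].enhancement == 0)

    def test_dt_self_convergence(self):
        patient = representative_subject(2.5)
        proto = timing_bolus()
        peaks = []
        for dt in (0.1, 0.05):
            s = SolverSettings(dt=dt, horizon=60.0)
            c = simulate(patient, proto, ["ascending_aorta"], s)[
                "ascending_aorta"]
            peaks.append(c.enhancement.max())
        assert abs(peaks[0] - peaks[1]) < 0.5  # HU

    def test_cohort_batch_matches_single(self):
        patients = [representative_subject(ci) for ci in (1.5, 3.0)]
        proto = timing_bolus()
        s = SolverSettings(horizon=40.0)
        batch = simulate_cohort(patients, proto, "ascending_aorta", s)
        for p, bc in zip(patients, batch):
            single = simulate(p, proto, ["ascending_aorta"], s)[
                "ascending_aorta"]
            # batch integration uses the batch-wide stability sub-step, so
            # agreement is at integration accuracy, not bitwise
            np.testing.assert_allclose(bc.enhancement, single.enhancement,
                                       rtol=2e-3,
                                       atol=1e-6 * single.enhancement.max())

    def test_higher_cardiac_output_arrives_earlier(self):
        from ctbolus.metrics import extract_metrics
        proto = timing_bolus()
        s = SolverSettings(horizon=70.0)
        ats = []
        for ci in (1.5, 2.5, 3.5):
            c = simulate(representative_subject(ci), proto,
                         ["ascending_aorta"], s)["ascending_aorta"]
            ats.append(extract_metrics(c).cm_at)
        assert ats[0] > ats[1] > ats[2]


class TestToHounsfield:
    def _curve(self, conc):
        t = np.arange(len(conc), dtype=float)
        return TimeDensityCurve(roi="x", time=t,
                                iodine_concentration=np.asarray(conc, float),
                                enhancement=np.zeros(len(conc)))

    def test_zero_concentration_gives_baseline(self):
        c = to_hounsfield(self._curve([0, 0, 0]), kappa=25.0, baseline=40.0)
        assert np.all(c.enhancement == 40.0)

    def test_linearity_in_kappa(self):
        base = self._curve([1.0, 2.0, 3.0])
        c1 = to_hounsfield(base, kappa=25.0)
        c2 = to_hounsfield(base, kappa=50.0)
        np.testing.assert_allclose(c2.enhancement, 2 * c1.enhancement)

    def test_350_hu_point(self):
        c = to_hounsfield(self._curve([14.0]), kappa=25.0)
        assert c.enhancement[0] == pytest.approx(350.0)

    def test_rejects_nonpositive_kappa(self):
        with pytest.raises(ValueError):
            to_hounsfield(self._curve([1.0]), kappa=0.0)
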
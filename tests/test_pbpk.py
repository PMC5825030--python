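"""Anthropometric formulas, protocol arithmetic, network scaling rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as stn

from ctbolus.pbpk import (
    IOPAMIDOL_370,
    ContrastAgent,
    InjectionProtocol,
    NetworkConfigError,
    PatientModel,
    adjust_to_cardiac_output,
    body_surface_area,
    build_reference_network,
    estimate_cardiac_output,
    required_cm_volume,
    scale_to_weight,
)

positive_dim = stn.floats(min_value=30.0, max_value=250.0)


class TestCardiacOutputEstimate:
    def test_frozen_values(self):
        # hand-evaluated 25.3 * H^0.725 * W^0.425 at high precision
        assert estimate_cardiac_output(170, 60) == pytest.approx(
            5969.11946100486, rel=1e-9)
        co = estimate_cardiac_output(166, 65.0)
        assert co == pytest.approx(6069.97722506323, rel=1e-9)
        assert 1000 < co < 10000

    @given(h=positive_dim, w=positive_dim)
    @hsettings(max_examples=50, derandomize=True, deadline=None)
    def test_power_law_homogeneity(self, h, w):
        ratio = estimate_cardiac_output(2 * h, w) / estimate_cardiac_output(
            h, w)
        assert ratio == pytest.approx(2 ** 0.725, rel=1e-12)

    @given(h=positive_dim, w=positive_dim)
    @hsettings(max_examples=50, derandomize=True, deadline=None)
    def test_estimated_cardiac_index_is_size_invariant(self, h, w):
        # same exponents in the CO and BSA power laws => constant ratio
        ratio = estimate_cardiac_output(h, w) / body_surface_area(h, w)
        assert ratio == pytest.approx(25.3 / 0.007184, rel=1e-12)
        assert ratio / 1000 == pytest.approx(3.5217, abs=2e-4)

    @pytest.mark.parametrize("h,w", [(-1, 60), (170, 0), (0, 0)])
    def test_rejects_nonpositive(self, h, w):
        with pytest.raises(ValueError):
            estimate_cardiac_output(h, w)
        with pytest.raises(ValueError):
            body_surface_area(h, w)


class TestBodySurfaceArea:
    def test_dubois_value(self):
        assert body_surface_area(166, 65.0) == pytest.approx(1.7236, abs=1e-3)

    @given(h=positive_dim, w=positive_dim)
    @hsettings(max_examples=25, derandomize=True, deadline=None)
    def test_positive(self, h, w):
        assert body_surface_area(h, w) > 0


class TestRequiredCmVolume:
    @pytest.mark.parametrize("dose,weight,conc,expected", [
        (245, 65.0, 350, 45.5),   # coronary CTA protocol
        (400, 65.0, 350, 74.3),   # abdominal CTA protocol
        (0, 65.0, 350, 0.0),
    ])
    def test_values(self, dose, weight, conc, expected):
        assert required_cm_volume(dose, weight, conc) == expected

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            required_cm_volume(245, 65, 0)


class TestPatientModel:
    def test_cardiac_index_consistency(self):
        p = PatientModel(height=166, weight=65, cardiac_output=3500)
        assert p.cardiac_index * p.body_surface_area * 1000 == pytest.approx(
            p.cardiac_output, rel=1e-9)

    def test_cardiac_output_estimated_when_absent(self):
        p = PatientModel(height=170, weight=60)
        assert p.cardiac_output == pytest.approx(
            estimate_cardiac_output(170, 60))

    def test_from_cardiac_index_round_trip(self):
        p = PatientModel.from_cardiac_index(166, 65, 2.5)
        assert p.cardiac_index == pytest.approx(2.5, rel=1e-12)


class TestInjectionProtocol:
    def test_rate_duration_duality(self):
        a = InjectionProtocol(cm_volume=45.5, agent=IOPAMIDOL_370,
                              injection_duration=10.0)
        b = InjectionProtocol(cm_volume=45.5, agent=IOPAMIDOL_370,
                              injection_rate=4.55)
        assert a.injection_rate == pytest.approx(4.55, rel=1e-12)
        assert b.injection_duration == pytest.approx(10.0, rel=1e-12)
        assert a.cm_volume == pytest.approx(
            a.injection_rate * a.injection_duration, rel=1e-9)

    def test_halving_duration_doubles_rate(self):
        slow = InjectionProtocol(cm_volume=45.5, agent=IOPAMIDOL_370,
                                 injection_duration=20.0)
        fast = InjectionProtocol(cm_volume=45.5, agent=IOPAMIDOL_370,
                                 injection_duration=10.0)
        assert fast.injection_rate == pytest.approx(2 * slow.injection_rate)

    def test_exactly_one_of_rate_or_duration(self):
        with pytest.raises(ValueError):
            InjectionProtocol(cm_volume=10, agent=IOPAMIDOL_370)
        with pytest.raises(ValueError):
            InjectionProtocol(cm_volume=10, agent=IOPAMIDOL_370,
                              injection_duration=5, injection_rate=2)

    def test_flush_defaults_to_injection_rate(self):
        p = InjectionProtocol(cm_volume=20, agent=IOPAMIDOL_370,
                              injection_rate=4.0, flush_volume=20)
        assert p.flush_rate == 4.0
        assert p.flush_duration == pytest.approx(5.0)


class TestContrastAgent:
    def test_osmolality_to_ratio(self):
        a = ContrastAgent("x", 350, 7.0, osmolality=590.0)
        assert a.osmotic_ratio == pytest.approx(590 / 290, rel=1e-12)

    def test_reference_agent_constants(self):
        assert IOPAMIDOL_370.iodine_concentration == 370
        assert IOPAMIDOL_370.osmotic_ratio == 2.76
        assert IOPAMIDOL_370.viscosity == 9.1


class TestReferenceNetwork:
    def test_left_heart_output(self, reference_network):
        assert reference_network.left_heart_output == pytest.approx(6500.0)

    def test_flow_balance_everywhere(self, reference_network):
        assert max(reference_network.flow_imbalance().values()) <= 1e-6

    def test_extra_organs_are_distinct(self, reference_network):
        names = {c.name for c in reference_network.compartments}
        assert {"stomach", "spleen", "pancreas", "myocardium"} <= names

    def test_systemic_inflows_sum_to_cardiac_output(self, reference_network):
        total = sum(q for s, _, q in reference_network.edges
                    if s == "ascending_aorta")
        assert total == pytest.approx(6500.0)

    def test_strongly_connected(self, reference_network):
        assert reference_network.is_strongly_connected()

    def test_malformed_table_names_compartment(self, tmp_path):
        bad = tmp_path / "compartments.tsv"
        bad.write_text("name\tblood_flow\tv_iv\tv_ec\tn_sub\tk_tc\n"
                       "oddity\t-5\t10\t0\t15\t0\n")
        with pytest.raises(NetworkConfigError, match="oddity"):
            build_reference_network(compartment_file=bad)


class TestScaling:
    def test_weight_identity_and_linearity(self, reference_network):
        same = scale_to_weight(reference_network, 60.0)
        assert same.left_heart_output == pytest.approx(6500.0)
        double = scale_to_weight(reference_network, 120.0)
        for c0, c2 in zip(reference_network.compartments,
                          double.compartments):
            assert c2.blood_flow == pytest.approx(2 * c0.blood_flow)
            assert c2.v_iv == pytest.approx(2 * c0.v_iv)
            assert c2.v_ec == pytest.approx(2 * c0.v_ec)

    def test_weight_65(self, reference_network):
        net = scale_to_weight(reference_network, 65.0)
        assert net.left_heart_output == pytest.approx(6500 * 65 / 60)

    def test_co_adjustment(self, reference_network):
        unchanged = adjust_to_cardiac_output(reference_network, 6500.0)
        assert unchanged.left_heart_output == pytest.approx(6500.0)
        halved = adjust_to_cardiac_output(reference_network, 3250.0)
        for c0, ch in zip(reference_network.compartments,
                          halved.compartments):
            assert ch.blood_flow == pytest.approx(0.5 * c0.blood_flow)
            assert ch.v_iv == c0.v_iv  # volumes untouched
        assert max(halved.flow_imbalance().values()) <= 1e-6

    def test_scale_and_adjust_commute(self, reference_network):
        a = adjust_to_cardiac_output(
            scale_to_weight(reference_network, 80.0), 4200.0)
        b = scale_to_weight(
            adjust_to_cardiac_output(reference_network, 4200.0 * 60 / 80),
            80.0)
        # route b: pre-adjusting so that the final weight scaling lands on
        # the same left-heart output
        assert a.left_heart_output == pytest.approx(4200.0)
        for ca, cb in zip(a.compartments, b.compartments):
            assert ca.blood_flow == pytest.approx(cb.blood_flow, rel=1e-12)
            assert ca.v_iv == pytest.approx(cb.v_iv, rel=1e-12)

    def test_rejects_nonpositive_targets(self, reference_network):
        with pytest.raises(ValueError):
            scale_to_weight(reference_network, 0)
        with pytest.raises(ValueError):
            adjust_to_cardiac_output(reference_network, -100)
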
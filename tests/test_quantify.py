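"""Quantification layer: DOL, quenching efficiency, internalization %, uptake,
eligibility and densitometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shipquant.errors import (
    InsufficientReplicatesError,
    InvalidMeasurementError,
    InvalidSpectrumError,
    ParameterError,
)
from shipquant.quantify import (
    DolInputs,
    QuenchPair,
    association,
    degree_of_labeling,
    densitometry_fraction,
    eligibility,
    internalization_percent,
    normalize_by_dol,
    quench_efficiency,
    uptake,
)
from shipquant.simulate import simulate_gel_lane


class TestDegreeOfLabeling:
    def test_no_dye_gives_zero(self):
        assert degree_of_labeling(DolInputs(0.0, 0.5, 250000, 210000)) == 0.0

    def test_hand_evaluated_value(self):
        # 0.25*210000 / (250000*(0.5 - 0.55*0.25)) = 52500/90625
        dol = degree_of_labeling(DolInputs(0.25, 0.5, 250000, 210000, cf=0.55))
        assert dol == pytest.approx(52500 / 90625)

    def test_default_correction_factor_is_cy5_fip(self):
        assert DolInputs(0.1, 0.5, 250000, 210000).cf == 0.55

    def test_dye_dominated_spectrum_rejected(self):
        with pytest.raises(InvalidSpectrumError):
            degree_of_labeling(DolInputs(1.0, 0.5, 250000, 210000, cf=0.55))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            DolInputs(-0.1, 0.5, 250000, 210000)
        with pytest.raises(ParameterError):
            DolInputs(0.1, 0.5, 0.0, 210000)


class TestDolNormalization:
    def test_identity_and_division(self):
        assert normalize_by_dol(100.0, 1.0) == 100.0
        assert normalize_by_dol(5701.0, 0.5) == pytest.approx(11402.0)

    def test_nonpositive_dol_rejected(self):
        with pytest.raises(ParameterError):
            normalize_by_dol(100.0, 0.0)


class TestQuenchEfficiency:
    def test_perfect_quench(self):
        qe = quench_efficiency(QuenchPair(p=1000.0, q=0.0, temperature="4C"))
        assert qe.q_eff == 1.0

    def test_hand_value(self):
        qe = quench_efficiency(QuenchPair(p=1000.0, q=30.0, temperature="4C"))
        assert qe.q_eff == pytest.approx(0.97)
        assert qe.residual_ratio == pytest.approx(0.03)

    def test_raw_ratio_exposed_when_clamped(self):
        qe = quench_efficiency(QuenchPair(p=100.0, q=120.0, temperature="4C"))
        assert qe.q_eff == 0.0
        assert qe.residual_ratio == pytest.approx(1.2)

    def test_requires_4c_pair(self):
        with pytest.raises(InvalidMeasurementError):
            quench_efficiency(QuenchPair(p=1000.0, q=30.0, temperature="37C"))

    def test_nonpositive_p_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            QuenchPair(p=0.0, q=30.0)


class TestInternalizationPercent:
    def test_pure_surface_is_zero(self):
        qe = 0.96
        pair = QuenchPair(p=1000.0, q=1000.0 * (1 - qe))
        assert internalization_percent(pair, qe).pct == pytest.approx(0.0, abs=1e-9)

    def test_fully_internal_is_hundred(self):
        pair = QuenchPair(p=1000.0, q=1000.0)
        assert internalization_percent(pair, 0.96).pct == pytest.approx(100.0)

    def test_hand_value(self):
        pair = QuenchPair(p=1000.0, q=700.0)
        assert internalization_percent(pair, 0.96).pct == pytest.approx(100 * (1 - 300 / 960))

    def test_zero_q_eff_directs_to_control(self):
        with pytest.raises(InvalidMeasurementError, match="4 °C control"):
            internalization_percent(QuenchPair(p=1000.0, q=700.0), 0.0)

    def test_clamping_keeps_raw_value(self):
        est = internalization_percent(QuenchPair(p=1000.0, q=10.0), 0.9)
        assert est.pct == 0.0 and est.raw_pct < 0.0

    def test_composition_identity_on_grid(self):
        # feeding the quencher model's exact expectations returns 100*f exactly
        s_n = 1234.5
        for f in np.linspace(0.0, 1.0, 11):
            for qe in (0.25, 0.5, 0.9, 0.96, 1.0):
                pair = QuenchPair(p=s_n, q=s_n * (f + (1 - f) * (1 - qe)))
                est = internalization_percent(pair, qe)
                assert est.raw_pct == pytest.approx(100 * f, abs=1e-9)

    @given(
        p=st.floats(min_value=1.0, max_value=1e6),
        q_frac=st.floats(min_value=0.0, max_value=1.0),
        qe=st.floats(min_value=0.05, max_value=1.0),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_invariant_to_common_rescaling(self, p, q_frac, qe, c):
        pair = QuenchPair(p=p, q=p * q_frac)
        scaled = QuenchPair(p=c * p, q=c * p * q_frac)
        a = internalization_percent(pair, qe).raw_pct
        b = internalization_percent(scaled, qe).raw_pct
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)

    @given(
        q1=st.floats(min_value=0.0, max_value=1000.0),
        q2=st.floats(min_value=0.0, max_value=1000.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_quenched_signal(self, q1, q2):
        lo, hi = sorted((q1, q2))
        a = internalization_percent(QuenchPair(p=1000.0, q=lo), 0.96).pct
        b = internalization_percent(QuenchPair(p=1000.0, q=hi), 0.96).pct
        assert b >= a


class TestUptakeAssociation:
    def test_definitions(self):
        pair = QuenchPair(p=1000.0, q=700.0)
        assert uptake(pair, 1.0) == 700.0
        assert association(pair, 1.0) == 1000.0
        assert uptake(QuenchPair(p=1.0, q=0.0), 2.0) == 0.0

    def test_pure_surface_quencher_identity(self):
        # under the quencher model, a surface-only pair has Q = P*(1 - q_eff)
        qe = 0.97
        pair = QuenchPair(p=5000.0, q=5000.0 * (1 - qe))
        assert uptake(pair) == pytest.approx(association(pair) * (1 - qe))


class TestEligibility:
    def test_identical_to_isotype_is_ineligible(self):
        res = eligibility([100.0, 101.0, 99.0], [100.0, 101.0, 99.0])
        assert not res.eligible

    def test_strong_association_is_eligible(self):
        res = eligibility([10000.0, 11000.0, 9000.0], [100.0, 110.0, 90.0])
        assert res.eligible and res.p_adjusted < 0.05

    def test_family_adjustment_with_other_groups(self):
        a = [1500.0, 1600.0, 1400.0]
        iso = [100.0, 110.0, 90.0]
        others = [[100.0 + i, 110.0 + i, 90.0 + i] for i in range(1, 6)]
        family = eligibility(a, iso, other_groups=others)
        assert family.eligible and 0.0 <= family.p_adjusted < 0.05

    def test_low_association_amid_bright_panel_still_detected(self):
        # a genuine 10x-over-background antibody must not be drowned by the
        # donor spread of a 1000x-over-background panel member (log scale)
        a = [1500.0, 1800.0, 1200.0]
        iso = [140.0, 170.0, 120.0]
        bright = [[140000.0, 260000.0, 80000.0]]
        res = eligibility(a, iso, other_groups=bright)
        assert res.eligible

    def test_below_isotype_mean_is_ineligible(self):
        res = eligibility([50.0, 60.0, 40.0], [100.0, 110.0, 90.0])
        assert not res.eligible

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            eligibility([1.0], [2.0, 3.0])


class TestDensitometry:
    def test_single_band_holds_nearly_all_signal(self):
        # the band window spans ±3 sigma, so ~0.3% of the Gaussian tails lie
        # outside it by construction
        lane = simulate_gel_lane({"complex": 1.0}, seed=0)
        assert densitometry_fraction(lane, "complex") >= 99.5

    def test_recovers_one_third_bound(self):
        lane = simulate_gel_lane(
            {"bound": 0.33, "free": 0.67},
            total_area=1000.0,
            band_centers={"bound": 40.0, "free": 70.0},
            band_widths=5.0,
            noise_sd=0.16,
            seed=4,
        )
        assert densitometry_fraction(lane, "bound") == pytest.approx(33.0, abs=1.5)

    def test_high_capture_band(self):
        lane = simulate_gel_lane(
            {"complex": 0.985, "free": 0.015},
            total_area=1000.0,
            band_centers={"complex": 40.0, "free": 70.0},
            band_widths=5.0,
            noise_sd=0.16,
            seed=4,
        )
        assert densitometry_fraction(lane, "complex") >= 97.0

    def test_band_fractions_sum_to_about_hundred(self):
        lane = simulate_gel_lane(
            {"a": 0.5, "b": 0.3, "c": 0.2},
            band_centers={"a": 25.0, "b": 60.0, "c": 95.0},
            band_widths=4.0,
            noise_sd=0.0,
            seed=0,
        )
        total = sum(densitometry_fraction(lane, b) for b in ("a", "b", "c"))
        assert total <= 100.0 + 1e-9
        assert total == pytest.approx(100.0, abs=1.0)

    def test_unknown_band_rejected(self):
        lane = simulate_gel_lane({"a": 1.0}, seed=0)
        with pytest.raises(ParameterError):
            densitometry_fraction(lane, "missing")
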
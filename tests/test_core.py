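"""Deterministic oCORM calculations: K, MCO, dCOHb, Hbmass, volumes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocorm import (
    AnalysisOptions,
    DegenerateMeasurementError,
    HematologyPanel,
    InvalidInputError,
    MissingDataError,
    RebreathingSession,
    analyze_session,
    compute_delta_cohb,
    compute_hbmass,
    compute_k,
    compute_mco,
    compute_uptake_fraction,
    compute_volumes,
)


def make_session(**kw):
    base = dict(
        subject_id="s1",
        k_factor=0.95,
        co_administered=40.0,
        co_lost=3.0,
        cohb_baseline=1.0,
        cohb_series=((3, 6.0), (6, 5.6), (8, 5.5), (10, 5.45), (12, 5.4), (15, 5.35)),
    )
    base.update(kw)
    return RebreathingSession(**base)


class TestComputeK:
    @pytest.mark.parametrize(
        "pressure, temperature, convention, expected",
        [
            (760, 0, "as_printed", 1.0),
            (760, 20, "as_printed", 1.07322),
            (760, 20, "stpd", 0.93178),
        ],
    )
    def test_examples(self, pressure, temperature, convention, expected):
        assert compute_k(pressure, temperature, convention) == pytest.approx(
            expected, abs=1e-5
        )

    def test_conventions_are_reciprocal_at_reference_pressure(self):
        k1 = compute_k(760, 25, "as_printed")
        k2 = compute_k(760, 25, "stpd")
        assert k1 * k2 == pytest.approx(1.0)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_k(0.0, 20)


class TestComputeMco:
    @pytest.mark.parametrize(
        "administered, lost, expected",
        [(35.0, 2.7, 32.3), (42.5, 0.0, 42.5), (87.9, 5.0, 82.9)],
    )
    def test_examples(self, administered, lost, expected):
        assert compute_mco(administered, lost) == pytest.approx(expected)

    def test_itemized_losses_are_summed(self):
        assert compute_mco(40.0, [2.0, 1.0, 0.5]) == pytest.approx(36.5)

    def test_losses_exceeding_dose_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_mco(10.0, 10.0)


class TestDeltaCohb:
    def test_mean_of_6_and_8_minus_baseline(self):
        s = make_session(
            cohb_baseline=1.35, cohb_series=((6, 6.40), (8, 6.40))
        )
        assert compute_delta_cohb(s) == pytest.approx(5.05)

    def test_unequal_samples(self):
        s = make_session(cohb_baseline=0.90, cohb_series=((6, 5.30), (8, 5.10)))
        assert compute_delta_cohb(s) == pytest.approx(4.30)

    def test_no_uptake_gives_zero(self):
        s = make_session(cohb_baseline=1.0, cohb_series=((6, 1.0),))
        assert compute_delta_cohb(s, sample_times=(6,)) == pytest.approx(0.0)

    def test_missing_timepoint_named_in_error(self):
        s = make_session(cohb_series=((6, 5.0),))
        with pytest.raises(MissingDataError, match="8"):
            compute_delta_cohb(s, sample_times=(6, 8))


class TestHbmass:
    def test_constants_cancel(self):
        assert compute_hbmass(1.0, 1.39, 1.0) == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "k, mco, delta, expected",
        [(0.923, 42.5, 4.30, 655.0), (0.931, 82.9, 4.50, 1234.0)],
    )
    def test_printed_subject_records(self, k, mco, delta, expected):
        assert compute_hbmass(k, mco, delta) == pytest.approx(expected, rel=0.005)

    def test_degenerate_measurement(self):
        with pytest.raises(DegenerateMeasurementError):
            compute_hbmass(1.0, 40.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        k=st.floats(0.85, 1.15),
        mco=st.floats(10, 120),
        delta=st.floats(2.0, 8.0),
        c=st.floats(1.1, 4.0),
    )
    def test_homogeneity_and_monotonicity(self, k, mco, delta, c):
        base = compute_hbmass(k, mco, delta)
        assert compute_hbmass(k, c * mco, delta) == pytest.approx(c * base, rel=1e-12)
        assert compute_hbmass(c * k, mco, delta) == pytest.approx(c * base, rel=1e-12)
        assert compute_hbmass(k, mco, c * delta) < base


class TestVolumes:
    def test_group_mean_scale_example(self):
        panel = HematologyPanel(hb_conc=15.0, hct=44.2, mchc=34.0)
        rcv, bv, pv = compute_volumes(901.0, panel)
        assert rcv == pytest.approx(2650, rel=0.001)
        assert bv == pytest.approx(6589, rel=0.001)
        assert pv == pytest.approx(3939, rel=0.001)

    def test_hand_arithmetic_with_unit_body_factor(self):
        panel = HematologyPanel(hb_conc=12.5, hct=50.0, mchc=25.0)
        rcv, bv, pv = compute_volumes(100.0, panel, body_hct_factor=1.0)
        assert (rcv, bv, pv) == (
            pytest.approx(400.0),
            pytest.approx(800.0),
            pytest.approx(400.0),
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        hbmass=st.floats(200, 1500),
        hct=st.floats(30, 55),
        mchc=st.floats(28, 38),
    )
    def test_conservation_exact(self, hbmass, hct, mchc):
        panel = HematologyPanel(hb_conc=mchc * hct / 100.0, hct=hct, mchc=mchc)
        rcv, bv, pv = compute_volumes(hbmass, panel)
        assert pv + rcv == bv  # exact by construction
        assert rcv < bv
        # the whole-body correction shrinks effective hematocrit, enlarging BV
        rcv1, bv1, _ = compute_volumes(hbmass, panel, body_hct_factor=1.0)
        assert bv > bv1
        assert rcv == rcv1


class TestUptakeFraction:
    @pytest.mark.parametrize(
        "administered, residual, expected",
        [(40.0, 3.2, 0.92), (40.0, 0.0, 1.0), (40.0, 40.0, 0.0)],
    )
    def test_examples(self, administered, residual, expected):
        assert compute_uptake_fraction(administered, residual) == pytest.approx(expected)

    def test_residual_above_dose_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_uptake_fraction(40.0, 41.0)


class TestSessionValidation:
    def test_duplicate_or_unordered_times_rejected(self):
        with pytest.raises(InvalidInputError):
            make_session(cohb_series=((6, 5.0), (6, 5.1)))
        with pytest.raises(InvalidInputError):
            make_session(cohb_series=((8, 5.0), (6, 5.1)))

    def test_below_baseline_flagged_not_fatal(self):
        s = make_session(cohb_baseline=5.0, cohb_series=((6, 4.0), (8, 6.0)))
        assert "cohb_below_baseline" in s.flags

    def test_losses_must_stay_below_dose(self):
        with pytest.raises(InvalidInputError):
            make_session(co_lost=41.0)

    def test_panel_mchc_consistency_enforced(self):
        with pytest.raises(InvalidInputError):
            HematologyPanel(hb_conc=15.0, hct=52.0, mchc=39.0)  # implies 28.8


class TestAnalyzeSession:
    def test_printed_records_forward(self, example_sessions):
        expected = {"subject_1": 429.0, "subject_2": 655.0, "subject_3": 1234.0}
        for session in example_sessions:
            result = analyze_session(session)
            assert result.hbmass_g == pytest.approx(
                expected[session.subject_id], rel=0.005
            )

    def test_supplied_k_used_verbatim(self):
        s = make_session(k_factor=0.934, pressure=760.0, temperature=20.0)
        assert analyze_session(s).k_factor == 0.934

    def test_safety_flag_above_10_percent(self):
        s = make_session(
            cohb_series=((3, 11.0), (6, 5.6), (8, 5.5), (10, 5.4), (12, 5.3), (15, 5.2))
        )
        result = analyze_session(s)
        assert any(w.startswith("cohb_above_10") for w in result.warnings)

    def test_volumes_require_panel(self):
        s = make_session()
        assert analyze_session(s).rcv_ml is None
        panel = HematologyPanel(hb_conc=15.0, hct=44.0)
        r = analyze_session(s, panel)
        assert r.pv_ml + r.rcv_ml == r.bv_ml

    def test_error_carries_session_id(self):
        s = make_session(subject_id="exam_42", cohb_series=((6, 5.0),))
        with pytest.raises(MissingDataError, match="exam_42"):
            analyze_session(s)

    def test_threshold_configurable(self):
        s = make_session()
        r = analyze_session(s, options=AnalysisOptions(safety_cohb_threshold=5.0))
        assert any(w.startswith("cohb_above_5") for w in r.warnings)
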
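"""Unit tests for the domain types and the two dilution-adjustment methods."""

import numpy as np
import pytest

import pushpull as pp
from pushpull.model import DegenerateTracerError, PushPullError


def make_series(time, **conc):
    return pp.BreakthroughSeries(
        time=np.asarray(time, float),
        concentrations={k: np.asarray(v, float) for k, v in conc.items()},
    )


def simple_design(ci1=100.0, ca1=1.0, ci2=50.0, ca2=0.5):
    return pp.TestDesign.from_solutes(
        [
            pp.SoluteSpec("tracer", "nonreactive", ci1, ca1),
            pp.SoluteSpec("target", "reactive", ci2, ca2),
        ]
    )


class TestValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(PushPullError, match="c_injection"):
            pp.SoluteSpec("x", "nonreactive", -1.0, 0.0)

    def test_unknown_role_rejected(self):
        with pytest.raises(PushPullError, match="role"):
            pp.SoluteSpec("x", "inert", 1.0, 0.0)

    def test_design_needs_a_nonreactive_solute(self):
        with pytest.raises(PushPullError, match="nonreactive"):
            pp.TestDesign.from_solutes([pp.SoluteSpec("x", "reactive", 1.0, 0.0)])

    def test_duplicate_solute_names_rejected(self):
        with pytest.raises(PushPullError, match="duplicate"):
            pp.TestDesign.from_solutes(
                [
                    pp.SoluteSpec("x", "nonreactive", 1.0, 0.0),
                    pp.SoluteSpec("x", "reactive", 1.0, 0.0),
                ]
            )

    def test_series_time_must_increase(self):
        with pytest.raises(PushPullError, match="strictly increasing"):
            make_series([0.0, 2.0, 1.0], tracer=[1, 1, 1])

    def test_series_rejects_negative_concentration(self):
        with pytest.raises(PushPullError, match="negative"):
            make_series([0.0, 1.0], tracer=[1.0, -0.5])

    def test_series_length_mismatch(self):
        with pytest.raises(PushPullError, match="samples"):
            pp.BreakthroughSeries(
                time=np.array([0.0, 1.0]),
                concentrations={"tracer": np.array([1.0])},
            )

    def test_volume_must_be_nondecreasing(self):
        with pytest.raises(PushPullError, match="nondecreasing"):
            pp.BreakthroughSeries(
                time=np.array([0.0, 1.0]),
                concentrations={"tracer": np.array([1.0, 1.0])},
                volume=np.array([5.0, 4.0]),
            )


class TestConventionalAdjust:
    def test_undiluted_sample_is_identity(self):
        # Ce1 = Ci1 at t=0 means no dilution: the target passes through.
        design = simple_design()
        series = make_series([0.0], tracer=[100.0], target=[50.0])
        adj = pp.conventional_adjust(series, design, "tracer", "target")
        assert adj.adjusted[0] == pytest.approx(50.0)
        assert adj.method == "conventional"
        assert adj.expected is None

    def test_twofold_tracer_dilution_doubles_target(self):
        design = simple_design()
        series = make_series([0.0, 1.0], tracer=[100.0, 50.0], target=[50.0, 20.0])
        adj = pp.conventional_adjust(series, design, "tracer", "target")
        np.testing.assert_allclose(adj.adjusted, [50.0, 40.0])

    def test_example3_overshoot_at_30h(self):
        # Frozen from direct evaluation of the dilution profile for both
        # solutes at t=30 h (kd=0.2/h) followed by the conventional formula:
        # Ce1 = 99 exp(-6)+1 = 1.2454, Ce2 = 45 exp(-6)+5 = 5.1115,
        # Ce2* = 5.1115*100/1.2454 = 410.44 -- far above the injected 50.
        design = simple_design(ca2=5.0)
        ce1 = 99.0 * np.exp(-6.0) + 1.0
        ce2 = 45.0 * np.exp(-6.0) + 5.0
        assert ce1 == pytest.approx(1.2454, abs=1e-4)
        assert ce2 == pytest.approx(5.1115, abs=1e-4)
        series = make_series([30.0], tracer=[ce1], target=[ce2])
        adj = pp.conventional_adjust(series, design, "tracer", "target")
        assert adj.adjusted[0] == pytest.approx(410.4, abs=0.05)

    def test_zero_tracer_sample_raises_with_location(self):
        design = simple_design()
        series = make_series([0.0, 1.0], tracer=[100.0, 0.0], target=[50.0, 10.0])
        with pytest.raises(PushPullError, match="sample 1"):
            pp.conventional_adjust(series, design, "tracer", "target")

    def test_reactive_tracer_rejected(self):
        design = simple_design()
        series = make_series([0.0], tracer=[100.0], target=[50.0])
        with pytest.raises(PushPullError, match="nonreactive"):
            pp.conventional_adjust(series, design, "target", "tracer")

    def test_unknown_solute_raises(self):
        design = simple_design()
        series = make_series([0.0], tracer=[100.0], target=[50.0])
        with pytest.raises(PushPullError, match="unknown solute"):
            pp.conventional_adjust(series, design, "tracer", "nope")


class TestExpectedConcentration:
    @pytest.mark.parametrize(
        "ce1, expected",
        [
            (100.0, 50.0),  # undiluted -> injected concentration
            (1.0, 5.0),  # fully diluted -> aquifer concentration
            (50.5, 27.5),  # midpoint: 0.5*45 + 5
        ],
    )
    def test_affine_map_endpoints_and_midpoint(self, ce1, expected):
        design = simple_design(ca2=5.0)
        series = make_series([0.0], tracer=[ce1], target=[0.0])
        ce2e = pp.expected_concentration(series, design, "tracer", "target")
        assert ce2e[0] == pytest.approx(expected)

    def test_degenerate_tracer_raises(self):
        design = pp.TestDesign.from_solutes(
            [
                pp.SoluteSpec("tracer", "nonreactive", 5.0, 5.0),
                pp.SoluteSpec("target", "reactive", 50.0, 0.5),
            ]
        )
        series = make_series([0.0], tracer=[5.0], target=[50.0])
        with pytest.raises(DegenerateTracerError):
            pp.expected_concentration(series, design, "tracer", "target")

    def test_monotone_tracer_gives_monotone_expectation(self):
        design = simple_design(ca2=5.0)
        ce1 = np.linspace(100.0, 1.0, 25)
        series = make_series(np.arange(25.0), tracer=ce1, target=np.zeros(25))
        ce2e = pp.expected_concentration(series, design, "tracer", "target")
        assert np.all(np.diff(ce2e) < 0)


class TestImprovedAdjust:
    def test_measured_equals_expected_gives_injected(self, example3):
        design, series = example3
        adj = pp.improved_adjust(series, design, "bromide", "ethanol")
        np.testing.assert_allclose(adj.adjusted, 50.0, rtol=1e-12)
        np.testing.assert_allclose(adj.expected, series.concentration("ethanol"))

    def test_reacting_target_recovers_pure_reaction_curve(self, example1):
        # With dilution and reaction both first-order, the improved-adjusted
        # curve is Ci2*exp(kr t): at t=5 h that is 50/e = 18.394 mg/L.
        design, series = example1
        adj = pp.improved_adjust(series, design, "bromide", "ethanol")
        k5 = int(np.flatnonzero(series.time == 5.0)[0])
        assert adj.adjusted[k5] == pytest.approx(50.0 * np.exp(-1.0), rel=1e-12)

    def test_nonpositive_expected_raises(self):
        # A tracer overshooting well below its (high) background drives the
        # affine expectation of a low-background target through zero.
        design = simple_design(ca1=50.0, ci2=50.0, ca2=0.5)
        series = make_series([0.0, 1.0], tracer=[100.0, 40.0], target=[50.0, 1.0])
        with pytest.warns(UserWarning, match="overshoots"):
            with pytest.raises(PushPullError, match="expected concentration"):
                pp.improved_adjust(series, design, "tracer", "target")


class TestDilutionFraction:
    def test_endpoints(self):
        design = simple_design()
        series = make_series([0.0, 99.0], tracer=[100.0, 1.0], target=[0.0, 0.0])
        frac = pp.dilution_fraction(series, design, "tracer")
        np.testing.assert_allclose(frac, [1.0, 0.0])

    def test_example1_tracer_at_5h(self, example1):
        design, series = example1
        frac = pp.dilution_fraction(series, design, "bromide")
        k5 = int(np.flatnonzero(series.time == 5.0)[0])
        assert series.concentration("bromide")[k5] == pytest.approx(37.42, abs=5e-3)
        assert frac[k5] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_overshoot_warns_not_raises(self):
        design = simple_design()
        series = make_series([0.0, 1.0], tracer=[100.0, 0.5], target=[0.0, 0.0])
        with pytest.warns(UserWarning, match="overshoots"):
            frac = pp.dilution_fraction(series, design, "tracer")
        assert frac[1] < 0


class TestRelativeBreakthrough:
    def test_reacting_target_breaks_through_less_than_tracer(self, example1):
        design, series = example1
        rb_tracer = pp.relative_breakthrough(series, design, "bromide")
        rb_target = pp.relative_breakthrough(series, design, "ethanol")
        assert rb_tracer[0] == pytest.approx(1.0)
        assert np.all(rb_target[1:] < rb_tracer[1:])

    def test_zero_injection_rejected(self):
        design = pp.TestDesign.from_solutes(
            [
                pp.SoluteSpec("tracer", "nonreactive", 100.0, 1.0),
                pp.SoluteSpec("target", "reactive", 0.0, 0.5),
            ]
        )
        series = make_series([0.0], tracer=[100.0], target=[0.0])
        with pytest.raises(PushPullError, match="c_injection"):
            pp.relative_breakthrough(series, design, "target")


class TestRatioAssumption:
    def test_equal_ratios_hold(self, example1):
        design, _ = example1
        rep = pp.check_ratio_assumption(design, "bromide", "ethanol")
        assert rep.tracer_ratio == pytest.approx(100.0)
        assert rep.target_ratio == pytest.approx(100.0)
        assert rep.relative_difference == pytest.approx(0.0)
        assert rep.holds

    def test_unequal_ratios_fail(self, example3):
        design, _ = example3
        rep = pp.check_ratio_assumption(design, "bromide", "ethanol")
        assert rep.tracer_ratio == pytest.approx(100.0)
        assert rep.target_ratio == pytest.approx(10.0)
        assert not rep.holds

    def test_tracer_against_itself_trivially_holds(self, example3):
        design, _ = example3
        rep = pp.check_ratio_assumption(design, "bromide", "bromide")
        assert rep.relative_difference == 0.0
        assert rep.holds

    def test_zero_background_flagged_not_raised(self):
        design = pp.TestDesign.from_solutes(
            [
                pp.SoluteSpec("tracer", "nonreactive", 100.0, 0.0),
                pp.SoluteSpec("target", "reactive", 50.0, 0.5),
            ]
        )
        rep = pp.check_ratio_assumption(design, "tracer", "target")
        assert rep.tracer_ratio is None
        assert not rep.holds
        assert "ratio undefined" in rep.reason
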
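"""TEF derivation, TEQ doses, and the additive mixture-effect model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pahteq as pq
from pahteq.errors import ExtrapolationError, InputError


class TestEquieffectiveDose:
    def test_exact_node_returns_observed_dose(self):
        curve = pq.DoseResponseCurve("x", ((1, 40), (10, 80)))
        assert pq.equieffective_dose(curve, 40) == 1.0

    def test_log_linear_midpoint(self):
        # halfway in effect between (1, 20) and (100, 60) lands on the
        # geometric mean of the doses
        curve = pq.DoseResponseCurve("x", ((1, 20), (100, 60)))
        assert pq.equieffective_dose(curve, 40) == pytest.approx(10.0)

    def test_above_maximum_raises(self):
        curve = pq.DoseResponseCurve("x", ((1, 20), (10, 50)))
        with pytest.raises(ExtrapolationError):
            pq.equieffective_dose(curve, 60)

    def test_zero_level_returns_zero_dose(self):
        curve = pq.DoseResponseCurve("x", ((1, 20), (10, 50)))
        assert pq.equieffective_dose(curve, 0) == 0.0

    def test_below_lowest_point_linear_from_origin(self):
        curve = pq.DoseResponseCurve("x", ((2, 20), (10, 50)))
        assert pq.equieffective_dose(curve, 10) == pytest.approx(1.0)

    def test_non_monotone_curve_is_isotonized(self):
        # the dip at 3 uM is noise; monotone cleanup pools it
        curve = pq.DoseResponseCurve("x", ((1, 30), (3, 25), (10, 60)))
        d = pq.equieffective_dose(curve, 40)
        assert 3 < d < 10

    def test_doses_must_increase(self):
        with pytest.raises(InputError):
            pq.DoseResponseCurve("x", ((5, 10), (1, 40)))


class TestComputeTefs:
    def test_study_equieffective_doses_give_printed_tefs(self, gjic_curves):
        """Equi-effective doses 1/10/20 uM at 40 % inhibition give the
        1.0 : 0.1 : 0.05 potency ranking."""
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        assert tefs.tefs["B[a]P"] == 1.0
        assert tefs.tefs["Flthn"] == pytest.approx(0.1)
        assert tefs.tefs["1-MeA"] == pytest.approx(0.05)
        assert tefs.ref_dose == pytest.approx(1.0)
        assert tefs.effect_level == 40.0

    def test_reference_tef_is_exactly_one(self, gjic_curves):
        tefs = pq.compute_tefs(gjic_curves, "Flthn", 40.0)
        assert tefs.tefs["Flthn"] == 1.0

    def test_tefs_invariant_to_common_dose_scaling(self, gjic_curves):
        scaled = {
            c: pq.DoseResponseCurve(c, tuple((2 * d, e) for d, e in cv.points))
            for c, cv in gjic_curves.items()
        }
        t1 = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        t2 = pq.compute_tefs(scaled, "B[a]P", 40.0)
        for c in t1.tefs:
            assert t1.tefs[c] == pytest.approx(t2.tefs[c])

    def test_missing_reference_raises(self, gjic_curves):
        with pytest.raises(InputError):
            pq.compute_tefs(gjic_curves, "pyrene", 40.0)

    def test_failing_curve_names_compound(self, gjic_curves):
        curves = dict(gjic_curves)
        curves["weak"] = pq.DoseResponseCurve("weak", ((1, 2), (10, 5)))
        with pytest.raises(ExtrapolationError, match="weak"):
            pq.compute_tefs(curves, "B[a]P", 40.0)


class TestTeqDose:
    def test_hand_computed_mixture(self, gjic_curves):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        mix = pq.MixtureSpec("m", {"B[a]P": 1, "Flthn": 5, "1-MeA": 5})
        assert pq.teq_dose(mix, tefs) == pytest.approx(1.75)

    def test_pure_reference_is_identity(self, gjic_curves):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        assert pq.teq_dose(pq.MixtureSpec("r", {"B[a]P": 3.2}), tefs) == pytest.approx(3.2)

    def test_empty_mixture_is_zero(self, gjic_curves):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        assert pq.teq_dose(pq.MixtureSpec("none", {}), tefs) == 0.0

    def test_unknown_compound_named_in_error(self, gjic_curves):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        with pytest.raises(InputError, match="pyrene"):
            pq.teq_dose(pq.MixtureSpec("m", {"pyrene": 1.0}), tefs)


class TestPredictAdditive:
    def test_printed_predictions(self, gjic_curves, study_mixtures):
        """The three tested combinations predict 43/55/70 % inhibition,
        i.e. 57/45/30 % fraction of control."""
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        preds = [pq.predict_additive(m, tefs) for m in study_mixtures]
        assert [round(p.predicted_inhibition) for p in preds] == [43, 55, 70]
        assert [round(p.predicted_foc) for p in preds] == [57, 45, 30]

    def test_anchor_identity(self, gjic_curves):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        p = pq.predict_additive(pq.MixtureSpec("a", {"B[a]P": tefs.ref_dose}), tefs)
        assert p.predicted_inhibition == pytest.approx(tefs.effect_level)

    def test_cap_at_100(self, gjic_curves):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        p = pq.predict_additive(pq.MixtureSpec("hot", {"B[a]P": 10}), tefs)
        assert p.predicted_inhibition == 100.0
        assert p.capped
        assert p.predicted_foc == 0.0

    @given(
        bap=st.floats(0, 1.2),
        flthn=st.floats(0, 5),
        mea=st.floats(0, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_effect_additivity_and_homogeneity(self, bap, flthn, mea):
        """Pre-cap, the mixture prediction equals the sum of single-compound
        predictions, and doubling all doses doubles TEQ and prediction."""
        tefs = pq.TefTable(
            reference="R", endpoint="e", ref_dose=1.0, effect_level=40.0,
            tefs={"R": 1.0, "F": 0.1, "M": 0.05},
        )
        doses = {"R": bap, "F": flthn, "M": mea}
        mix = pq.MixtureSpec("m", doses)
        total = sum(
            pq.predict_additive(pq.MixtureSpec(c, {c: d}), tefs).predicted_inhibition
            for c, d in doses.items()
        )
        pred = pq.predict_additive(mix, tefs)
        if not pred.capped and total <= 100:
            assert pred.predicted_inhibition == pytest.approx(total)
            assert pred.predicted_foc == pytest.approx(100 - pred.predicted_inhibition)
        double = pq.predict_additive(
            pq.MixtureSpec("m2", {c: 2 * d for c, d in doses.items()}), tefs
        )
        assert double.teq_dose == pytest.approx(2 * pred.teq_dose)


class TestComparePredictions:
    def test_printed_observed_triple(self, gjic_curves, study_mixtures):
        """Observed inhibition 47/62/66 % deviates +4/+7/-4 points from the
        additive predictions; mean absolute deviation 5 points."""
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        preds = [pq.predict_additive(m, tefs) for m in study_mixtures]
        comp = pq.compare_predictions(
            preds, {"combo_1": 47, "combo_5": 62, "combo_10": 66}
        )
        assert [round(r.deviation) for r in comp.rows] == [4, 7, -4]
        assert comp.mean_abs_deviation == pytest.approx(5.0)

    def test_identical_observation_zero_deviation(self, gjic_curves, study_mixtures):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        preds = [pq.predict_additive(m, tefs) for m in study_mixtures]
        comp = pq.compare_predictions(
            preds, {p.mixture: p.predicted_inhibition for p in preds}
        )
        assert comp.mean_abs_deviation == 0.0

    def test_unmatched_label_raises(self, gjic_curves, study_mixtures):
        tefs = pq.compute_tefs(gjic_curves, "B[a]P", 40.0)
        preds = [pq.predict_additive(study_mixtures[0], tefs)]
        with pytest.raises(InputError):
            pq.compare_predictions(preds, {"nope": 50.0})


class TestMisapplicationRatio:
    def test_carcinogenicity_tef_understates_cocarcinogenic_potency(self):
        # fluoranthene: 0.1 for the gap-junction endpoint vs 0.001 for
        # carcinogenicity -> 100-fold misstatement
        assert pq.tef_misapplication_ratio(0.1, 0.001) == pytest.approx(100.0)

    def test_equal_tefs_give_unity(self):
        assert pq.tef_misapplication_ratio(0.05, 0.05) == 1.0

    def test_nonpositive_tef_raises(self):
        with pytest.raises(InputError):
            pq.tef_misapplication_ratio(0.0, 0.1)


@given(
    doses=st.lists(st.floats(0.01, 100), min_size=2, max_size=6, unique=True),
    effects=st.lists(st.floats(1, 99), min_size=2, max_size=6),
    level_frac=st.floats(0.05, 0.95),
)
@settings(max_examples=100, deadline=None)
def test_reference_tef_is_one_under_any_monotone_curve(doses, effects, level_frac):
    n = min(len(doses), len(effects))
    doses, effects = sorted(doses)[:n], sorted(effects)[:n]
    if len(doses) < 2 or len(set(effects)) < 2:
        return
    curve = pq.DoseResponseCurve("ref", tuple(zip(doses, effects)))
    level = effects[0] + level_frac * (effects[-1] - effects[0])
    tefs = pq.compute_tefs({"ref": curve}, "ref", level)
    assert tefs.tefs["ref"] == 1.0
    d = pq.equieffective_dose(curve, level)
    assert doses[0] <= d <= doses[-1] or math.isclose(d, doses[0])
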
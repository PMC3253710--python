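"""Step-function evaluation, active terms, focal positions and validation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpltol.model import (
    Equation,
    LandmarkScale,
    MAX,
    ModelError,
    PLModel,
    QualitativeState,
    StepLiteral,
    SynthesisTerm,
    Variable,
    ZERO,
    active_terms,
    eval_step,
    focal_landmark,
    focal_landmark_symbol,
    focal_position,
    threshold_landmark,
    validate_model,
)
from qpltol.qsim import enumerate_states
from qpltol.synth import random_model
from qpltol.tol import build_tol_model


def _state(model, **levels):
    return model.make_state(levels)


class TestEvalStep:
    def test_positive_literal_above_threshold(self, tol_wt_high):
        s = _state(tol_wt_high, XylR=1)
        assert eval_step(StepLiteral("XylR", "theta_XylR", "+"), s, tol_wt_high) == 1

    def test_positive_literal_below_threshold(self, tol_wt_high):
        s = _state(tol_wt_high, XylR=0)
        assert eval_step(StepLiteral("XylR", "theta_XylR", "+"), s, tol_wt_high) == 0

    def test_negative_literal_is_complement_above(self, tol_wt_high):
        s = _state(tol_wt_high, XylR=1)
        assert eval_step(StepLiteral("XylR", "theta_XylR", "-"), s, tol_wt_high) == 0

    def test_basal_xyls_does_not_clear_hyperexpression_threshold(self, tol_wt_high):
        # XylS between its two thresholds: above theta1 (effector-responsive)
        # but below theta2, the level needed to trigger Pm on its own
        s = _state(tol_wt_high, XylS=1)
        assert eval_step(StepLiteral("XylS", "theta2_XylSh", "+"), s, tol_wt_high) == 0
        assert eval_step(StepLiteral("XylS", "theta1_XylSi", "+"), s, tol_wt_high) == 1

    def test_unknown_threshold_raises(self, tol_wt_high):
        s = tol_wt_high.make_state()
        with pytest.raises(ModelError):
            eval_step(StepLiteral("XylR", "theta_upper", "+"), s, tol_wt_high)

    def test_step_complement_identity(self, tol_wt_high):
        """s+ and s- sum to 1 for every (variable, threshold, state)."""
        for state in enumerate_states(tol_wt_high):
            for v in tol_wt_high.variables:
                for th in v.thresholds:
                    pos = eval_step(StepLiteral(v.name, th, "+"), state, tol_wt_high)
                    neg = eval_step(StepLiteral(v.name, th, "-"), state, tol_wt_high)
                    assert pos + neg == 1


class TestActiveTerms:
    def test_xyls_fully_induced(self, tol_wt_high):
        eq = tol_wt_high.equation("XylS")
        s = _state(tol_wt_high, XylR=1)
        assert active_terms(eq, s, tol_wt_high) == {"k0_XylS", "k1_XylS"}

    def test_xyls_basal_without_inducer(self, tol_wt_low):
        eq = tol_wt_low.equation("XylS")
        s = _state(tol_wt_low, XylR=1)
        assert active_terms(eq, s, tol_wt_low) == {"k0_XylS"}

    def test_upper_and_gate_blocked_without_inducer(self, tol_wt_low):
        eq = tol_wt_low.equation("upper")
        s = _state(tol_wt_low, XylR=1)
        assert active_terms(eq, s, tol_wt_low) == frozenset()

    def test_constitutive_always_active(self, tol_wt_low):
        eq = tol_wt_low.equation("XylR")
        assert active_terms(eq, tol_wt_low.make_state(), tol_wt_low) == {"k0_XylR"}


class TestFocalPosition:
    def test_hyperexpressed_xyls_targets_top_interval(self, tol_wt_high):
        # both terms active: (k0+k1)/g lies above theta2_XylSh
        eq = tol_wt_high.equation("XylS")
        s = _state(tol_wt_high, XylR=1)
        assert focal_position(eq, s, tol_wt_high) == 2

    def test_meta_single_term_focal_between_landmarks(self, tol_wt_high):
        # only the effector branch on: focal k1_meta/g_meta is above
        # theta_meta but below the fully induced level
        eq = tol_wt_high.equation("meta")
        s = _state(tol_wt_high, XylS=1, upper=1, XylR=1)
        assert active_terms(eq, s, tol_wt_high) == {"k1_meta"}
        assert focal_position(eq, s, tol_wt_high) == 1
        scale = tol_wt_high.scale("meta")
        lm = focal_landmark(eq, s, tol_wt_high)
        assert lm.display() == "k1_meta/g_meta"
        below = scale.position(focal_landmark_symbol({"k0_meta"}, "g_meta"))
        above = scale.position(focal_landmark_symbol({"k0_meta", "k1_meta"}, "g_meta"))
        assert below < scale.position(lm) < above

    def test_no_active_terms_decays_to_zero_interval(self, tol_wt_high):
        eq = tol_wt_high.equation("upper")
        s = tol_wt_high.make_state()
        assert focal_position(eq, s, tol_wt_high) == 0
        assert focal_landmark(eq, s, tol_wt_high).kind == "zero"

    def test_focal_depends_only_on_active_set(self, tol_wt_high):
        """States with the same active-term set share a focal interval."""
        eq = tol_wt_high.equation("meta")
        by_active = {}
        for state in enumerate_states(tol_wt_high):
            key = active_terms(eq, state, tol_wt_high)
            by_active.setdefault(key, set()).add(
                focal_position(eq, state, tol_wt_high))
        assert all(len(vals) == 1 for vals in by_active.values())

    @settings(max_examples=40, derandomize=True)
    @given(upper=st.integers(0, 1), xyls=st.integers(0, 2),
           meta=st.integers(0, 1), xylr=st.integers(0, 1))
    def test_focal_interval_contains_its_landmark(self, upper, xyls, meta, xylr):
        """For every state, the focal landmark's interval equals the focal
        position — the two accessors agree across the whole state space."""
        model = build_tol_model()
        s = model.make_state({"upper": upper, "XylS": xyls,
                              "meta": meta, "XylR": xylr})
        for eq in model.equations:
            lm = focal_landmark(eq, s, model)
            scale = model.scale(eq.variable)
            assert focal_position(eq, s, model) == scale.interval_of(lm)

    @pytest.mark.parametrize("seed", range(8))
    def test_adding_terms_never_lowers_focal(self, seed):
        """Monotonicity: on every scale, focal landmarks of nested subsets
        keep the subset order (forced by the scale invariant)."""
        model = random_model(3, 2, 0.8, seed)
        for v in model.state_variables:
            scale = model.scale(v.name)
            focals = [l for l in scale.landmarks if l.kind == "focal"]
            for a, b in itertools.combinations(focals, 2):
                if a.rates < b.rates:
                    assert scale.position(a) < scale.position(b)
                    assert scale.interval_of(a) <= scale.interval_of(b)


class TestValidateModel:
    def test_packaged_tol_models_validate_cleanly(self, tol_models):
        for model in tol_models.values():
            assert validate_model(model) == []

    def test_missing_focal_landmark_is_reported(self, tol_wt_high):
        broken = build_tol_model()
        scale = broken.scales["XylS"]
        target = focal_landmark_symbol({"k0_XylS", "k1_XylS"}, "g_XylS")
        broken.scales["XylS"] = LandmarkScale(
            "XylS", tuple(l for l in scale.landmarks if l != target))
        diags = validate_model(broken)
        assert any(d.code == "missing-focal" and "k1_XylS" in d.symbol
                   for d in diags)

    def test_removed_threshold_names_the_symbol(self):
        broken = build_tol_model()
        scale = broken.scales["XylS"]
        broken.scales["XylS"] = LandmarkScale(
            "XylS",
            tuple(l for l in scale.landmarks if l.label != "theta2_XylSh"))
        diags = validate_model(broken)
        assert any("theta2_XylSh" in d.symbol for d in diags)

    def test_literal_with_foreign_threshold(self):
        broken = build_tol_model()
        eq = broken.equation("upper")
        bad = Equation("upper",
                       (SynthesisTerm("k0_upper",
                                      (StepLiteral("XylR", "theta_upper", "+"),)),),
                       "g_upper")
        broken.equations[broken.equations.index(eq)] = bad
        diags = validate_model(broken)
        assert any(d.code == "literal-threshold" for d in diags)

    def test_missing_clamp_detected(self):
        broken = build_tol_model()
        broken.clamps = {}
        diags = validate_model(broken)
        assert any(d.code == "missing-clamp" and d.symbol == "m_xyl"
                   for d in diags)

    def test_duplicate_landmark_breaks_strictness(self):
        broken = build_tol_model()
        scale = broken.scales["XylR"]
        dup = scale.landmarks[:2] + (scale.landmarks[1],) + scale.landmarks[2:]
        broken.scales["XylR"] = LandmarkScale("XylR", dup)
        diags = validate_model(broken)
        assert any(d.code == "scale-tie" for d in diags)

    def test_input_with_equation_rejected(self):
        model = PLModel(
            variables=[Variable("u", "input", ("theta_u",))],
            equations=[Equation("u", (SynthesisTerm("k_u"),), "g_u")],
            scales={"u": LandmarkScale("u", (ZERO, threshold_landmark("theta_u"), MAX))},
            clamps={"u": 0},
        )
        diags = validate_model(model)
        assert any(d.code == "input-equation" for d in diags)


class TestQualitativeState:
    def test_states_are_hashable_and_orderable(self):
        a = QualitativeState(("x", "y"), (0, 1))
        b = QualitativeState(("x", "y"), (0, 1))
        c = QualitativeState(("x", "y"), (1, 0))
        assert a == b and hash(a) == hash(b)
        assert a < c
        assert len({a, b, c}) == 2

    def test_with_level_is_functional(self):
        a = QualitativeState(("x", "y"), (0, 1))
        b = a.with_level("x", 2)
        assert a.levels == (0, 1) and b.levels == (2, 1)
        with pytest.raises(ModelError):
            a.level("z")
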
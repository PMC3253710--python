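"""Numerical certification: sampling, closed-form integration, soundness."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from qpltol.model import (
    Equation,
    LandmarkScale,
    MAX,
    PLModel,
    QualitativeState,
    SynthesisTerm,
    Variable,
    ZERO,
    focal_landmark_symbol,
    threshold_landmark,
)
from qpltol.oracle import (
    EVENT_TOL,
    audit_model,
    check_soundness,
    discretize,
    integrate_pl,
    qualitative_state_at,
    sample_parameters,
)
from qpltol.qsim import build_stg, steady_states
from qpltol.synth import make_toggle_switch, random_model
from qpltol.tol import TOLCondition, build_tol_model


def _single_riser():
    """One constitutive variable: dx/dt = k - g x."""
    return PLModel(
        variables=[Variable("x", "state", ("theta_x",))],
        equations=[Equation("x", (SynthesisTerm("k_x"),), "g_x")],
        scales={"x": LandmarkScale("x", (
            ZERO, threshold_landmark("theta_x"),
            focal_landmark_symbol({"k_x"}, "g_x"), MAX))},
        name="single-riser",
    )


def _numeric_rhs(model, sample):
    """Independent numeric vector field built directly from the step-function
    definition, for cross-validation with a generic stiff integrator."""
    svars = [v.name for v in model.state_variables]

    def clamp_value(name):
        var = model.variable(name)
        th = sample[var.thresholds[0]]
        return 2 * th if model.clamps.get(name, 0) > 0 else 0.5 * th

    def rhs(t, x):
        conc = dict(zip(svars, x))
        for v in model.input_variables:
            conc[v.name] = clamp_value(v.name)
        out = []
        for n in svars:
            eq = model.equation(n)
            syn = 0.0
            for term in eq.synthesis:
                gate = 1.0
                for l in term.literals:
                    bit = 1.0 if conc[l.variable] > sample[l.threshold] else 0.0
                    gate *= bit if l.sign == "+" else 1.0 - bit
                syn += sample[term.rate] * gate
            out.append(syn - sample[eq.degradation_rate] * conc[n])
        return out

    return rhs


class TestSampling:
    def test_same_seed_is_identical(self, tol_wt_high):
        a = sample_parameters(tol_wt_high, 7)
        b = sample_parameters(tol_wt_high, 7)
        assert a.values == b.values

    def test_different_seeds_differ(self, tol_wt_high):
        assert sample_parameters(tol_wt_high, 1).values != \
            sample_parameters(tol_wt_high, 2).values

    @pytest.mark.parametrize("seed", range(25))
    def test_sample_satisfies_every_scale_order(self, tol_models, seed):
        for model in tol_models.values():
            sample = sample_parameters(model, seed)
            for v in model.variables:
                scale = model.scale(v.name)
                vals = [sample.landmark_value(model, v.name, lm)
                        for lm in scale.landmarks]
                assert all(a < b for a, b in zip(vals, vals[1:])), \
                    (model.name, v.name, vals)

    def test_induced_hyperexpression_order_holds_numerically(self, tol_wt_high):
        s = sample_parameters(tol_wt_high, 1)
        assert s["theta2_XylSh"] < (s["k0_XylS"] + s["k1_XylS"]) / s["g_XylS"]

    def test_samples_cover_random_models(self):
        for seed in range(10):
            model = random_model(3, 2, 0.7, seed)
            sample = sample_parameters(model, seed + 1)
            for v in model.variables:
                scale = model.scale(v.name)
                vals = [sample.landmark_value(model, v.name, lm)
                        for lm in scale.landmarks]
                assert all(a < b for a, b in zip(vals, vals[1:]))


class TestIntegration:
    def test_single_riser_matches_the_log_crossing_formula(self):
        model = _single_riser()
        sample = sample_parameters(model, 3)
        k, g, theta = sample["k_x"], sample["g_x"], sample["theta_x"]
        traj = integrate_pl(model, sample, t_end=200.0)
        assert traj.terminal == "converged"
        # the single event is the crossing of theta at t* = ln(phi/(phi-theta))/g
        phi = k / g
        t_star = math.log((0 - phi) / (theta - phi)) / g
        assert traj.segments[0].t1 == pytest.approx(t_star, rel=1e-12)
        assert traj.final[0] == pytest.approx(phi, rel=1e-6)

    def test_nonnegative_x0_and_positive_t_end_required(self):
        model = _single_riser()
        sample = sample_parameters(model, 3)
        with pytest.raises(ValueError):
            integrate_pl(model, sample, x0={"x": -1.0})
        with pytest.raises(ValueError):
            integrate_pl(model, sample, t_end=0.0)

    @pytest.mark.parametrize("builder,seed", [
        (lambda: build_tol_model(TOLCondition("wild_type", "high")), 1),
        (lambda: build_tol_model(TOLCondition("wild_type", "low")), 2),
        (lambda: make_toggle_switch()[0], 3),
    ])
    def test_closed_form_matches_stiff_integrator(self, builder, seed):
        """Event-driven integration agrees with scipy LSODA on the same
        vector field to better than 1e-6 relative at the endpoint."""
        model = builder()
        sample = sample_parameters(model, seed)
        t_end = 60.0
        traj = integrate_pl(model, sample, t_end=t_end)
        assert traj.terminal != "sliding_detected"
        sol = solve_ivp(_numeric_rhs(model, sample), (0.0, t_end),
                        np.zeros(len(traj.variables)), method="LSODA",
                        rtol=1e-10, atol=1e-12, max_step=0.05)
        ours = traj.final if traj.terminal == "converged" else traj.x_at(t_end)
        ref = sol.y[:, -1]
        assert np.max(np.abs(ours - ref) / np.maximum(np.abs(ref), 1e-8)) < 1e-6

    def test_induced_wild_type_ends_all_high(self, tol_wt_high):
        sample = sample_parameters(tol_wt_high, 11)
        traj = integrate_pl(tol_wt_high, sample, t_end=200.0)
        assert traj.terminal == "converged"
        final = dict(zip(traj.variables, traj.final))
        assert final["upper"] > sample["theta_upper"]
        assert final["XylS"] > sample["theta2_XylSh"]
        assert final["meta"] > sample["theta_meta"]
        assert final["XylR"] > sample["theta_XylR"]

    def test_no_xylsh_meta_converges_to_the_single_term_focal(self):
        model = build_tol_model(TOLCondition("no_xylsh", "high"))
        sample = sample_parameters(model, 5)
        traj = integrate_pl(model, sample, t_end=300.0)
        assert traj.terminal == "converged"
        meta = traj.final[list(traj.variables).index("meta")]
        assert meta == pytest.approx(sample["k1_meta"] / sample["g_meta"],
                                     rel=1e-6)


class TestDiscretize:
    def test_starts_at_the_all_zero_state(self, tol_wt_high):
        sample = sample_parameters(tol_wt_high, 4)
        traj = integrate_pl(tol_wt_high, sample, t_end=200.0)
        seq = discretize(traj, tol_wt_high)
        assert seq[0] == tol_wt_high.make_state()

    def test_terminal_state_is_an_stg_steady_state(self, tol_wt_high):
        stg = build_stg(tol_wt_high)
        sample = sample_parameters(tol_wt_high, 4)
        traj = integrate_pl(tol_wt_high, sample, t_end=200.0)
        seq = discretize(traj, tol_wt_high)
        assert seq[-1] in steady_states(stg)
        # the landmark interval of the steady state contains the numeric value
        assert qualitative_state_at(
            tol_wt_high, sample, traj.final, traj.variables) == seq[-1]

    def test_trajectory_inside_one_domain_collapses_to_one_state(self):
        model = _single_riser()
        sample = sample_parameters(model, 3)
        # start above the threshold, already in the focal domain
        phi = sample["k_x"] / sample["g_x"]
        traj = integrate_pl(model, sample, x0={"x": phi * 0.999}, t_end=50.0)
        assert len(discretize(traj, model)) == 1


class TestSoundness:
    def test_empty_sequence_passes(self, tol_wt_high):
        assert check_soundness(build_stg(tol_wt_high), []).passed

    def test_simultaneous_double_jump_is_flagged(self, tol_wt_high):
        stg = build_stg(tol_wt_high)
        names = tol_wt_high.variable_names
        a = tol_wt_high.make_state()
        b = tol_wt_high.make_state({"XylR": 1, "XylS": 1})  # two moves at once
        res = check_soundness(stg, [a, b])
        assert not res.passed
        assert res.violation == (a, b)

    @pytest.mark.parametrize("cond", [
        ("wild_type", "low"), ("wild_type", "high"),
        ("no_xylsh", "high"), ("no_xylsa", "high")])
    def test_audit_over_seeds_is_fully_sound(self, tol_models, cond):
        """Headline certification: discretized numerical trajectories are STG
        paths ending in a steady state, across seeds and scenarios."""
        model = tol_models[cond]
        stg = build_stg(model)
        df = audit_model(model, stg, n_seeds=12, t_end=200.0, base_seed=0)
        assert df["sound"].all()
        assert (df["terminal"] == "converged").all()
        assert df["steady_ok"].all()
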
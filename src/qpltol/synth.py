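"""Synthetic PL fixtures with known qualitative behavior.

Canonical circuits (activation cascades, a bistable toggle switch, a
single-input fan-out) and seeded random models exercise every engine
operation without any external data.  Random models are generated from a
concrete numeric instantiation — rates, degradation constants and thresholds
are drawn first and the symbolic landmark order is read off the numbers — so
every emitted scale order is realizable by actual parameter values (an
arbitrary linear extension of the subset lattice need not be), and the
numerical oracle is guaranteed a consistent sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import (
    MAX,
    ZERO,
    Equation,
    Landmark,
    LandmarkScale,
    PLModel,
    QualitativeState,
    StepLiteral,
    SynthesisTerm,
    Variable,
    focal_landmark_symbol,
    threshold_landmark,
    validate_model,
)
from .qsim import build_stg, steady_states


@dataclass(frozen=True)
class FixtureSpec:
    """What a generated fixture is expected to do, verifiable by the engine:
    a steady-state count and 'A rises before B' ordering constraints."""

    name: str
    expected_steady_count: int
    ordering: tuple[tuple[str, str], ...] = ()   # (earlier, later) pairs
    params: dict = field(default_factory=dict)


def verify_fixture(model: PLModel, spec: FixtureSpec,
                   initial: QualitativeState | None = None) -> dict:
    """Check a fixture's expectations on its own STG.

    An ordering constraint (A, B) holds iff no reachable state has B above 0
    while A is still at 0 — with unit steps and an all-zero start this is
    exactly 'A rises before B on every path'.
    """
    stg = build_stg(model, initial)
    steadies = steady_states(stg)
    ordering_ok = {}
    for a, b in spec.ordering:
        ordering_ok[f"{a}<{b}"] = all(
            s.level(a) > 0 for s in stg.graph.nodes if s.level(b) > 0
        )
    return {
        "n_steady": len(steadies),
        "steady_count_ok": len(steadies) == spec.expected_steady_count,
        "ordering_ok": ordering_ok,
        "all_ok": len(steadies) == spec.expected_steady_count
        and all(ordering_ok.values()),
    }


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def _simple_scale(var: str, rate_subsets: list[frozenset[str]], deg: str,
                  threshold_below_focals: bool = True) -> LandmarkScale:
    """zero < theta_var < focals... < max (activating order), or with the
    threshold above every focal when the variable must never switch on."""
    th = threshold_landmark(f"theta_{var}")
    focals = [focal_landmark_symbol(s, deg) for s in rate_subsets]
    if threshold_below_focals:
        order = (ZERO, th, *focals, MAX)
    else:
        order = (ZERO, *focals, th, MAX)
    return LandmarkScale(var, order)


def make_cascade(n: int, gate_with_input: bool = False) -> tuple[PLModel, FixtureSpec]:
    """Linear activation chain x1 -> x2 -> ... -> xn under one clamped input.

    x1 is gated by the input; each later stage by its predecessor (AND the
    input as well when ``gate_with_input``).  Expected: a unique steady state
    with every stage high, reached with the strict order x1 before x2 before
    ... before xn on every path.
    """
    if n < 1:
        raise ValueError("cascade needs n >= 1")
    names = [f"x{i}" for i in range(1, n + 1)]
    variables = [Variable("inp", "input", ("theta_inp",))]
    variables += [Variable(v, "state", (f"theta_{v}",)) for v in names]
    equations = []
    scales = {"inp": LandmarkScale("inp", (ZERO, threshold_landmark("theta_inp"), MAX))}
    for i, v in enumerate(names):
        lits = [StepLiteral("inp", "theta_inp", "+")] if i == 0 else (
            ([StepLiteral("inp", "theta_inp", "+")] if gate_with_input else [])
            + [StepLiteral(names[i - 1], f"theta_{names[i - 1]}", "+")]
        )
        rate, deg = f"k_{v}", f"g_{v}"
        equations.append(Equation(v, (SynthesisTerm(rate, tuple(lits)),), deg))
        scales[v] = _simple_scale(v, [frozenset({rate})], deg)
    model = PLModel(variables, equations, scales, clamps={"inp": 1},
                    name=f"cascade-{n}")
    spec = FixtureSpec(
        name=model.name,
        expected_steady_count=1,
        ordering=tuple(zip(names, names[1:])),
        params={"n": n, "gate_with_input": gate_with_input},
    )
    return model, spec


def make_sim_fanout(n_targets: int = 2) -> tuple[PLModel, FixtureSpec]:
    """Single-input module: one constitutively rising regulator gating
    ``n_targets`` targets through the *same* threshold, so every target's
    synthesis term switches on in the same qualitative state."""
    if n_targets < 1:
        raise ValueError("fan-out needs at least one target")
    targets = [f"y{i}" for i in range(1, n_targets + 1)]
    variables = [Variable("reg", "state", ("theta_reg",))]
    variables += [Variable(t, "state", (f"theta_{t}",)) for t in targets]
    equations = [Equation("reg", (SynthesisTerm("k_reg"),), "g_reg")]
    scales = {"reg": _simple_scale("reg", [frozenset({"k_reg"})], "g_reg")}
    for t in targets:
        rate, deg = f"k_{t}", f"g_{t}"
        equations.append(Equation(
            t, (SynthesisTerm(rate, (StepLiteral("reg", "theta_reg", "+"),)),), deg))
        scales[t] = _simple_scale(t, [frozenset({rate})], deg)
    model = PLModel(variables, equations, scales, name=f"sim-fanout-{n_targets}")
    spec = FixtureSpec(name=model.name, expected_steady_count=1,
                       params={"n_targets": n_targets})
    return model, spec


def make_toggle_switch() -> tuple[PLModel, FixtureSpec]:
    """Two mutually repressing variables (negative step literals),
    constitutive synthesis; bistable: exactly two steady states, each with
    one variable high, both reachable from the symmetric off-state."""
    variables = [Variable("u", "state", ("theta_u",)),
                 Variable("v", "state", ("theta_v",))]
    equations = [
        Equation("u", (SynthesisTerm("k_u", (StepLiteral("v", "theta_v", "-"),)),),
                 "g_u"),
        Equation("v", (SynthesisTerm("k_v", (StepLiteral("u", "theta_u", "-"),)),),
                 "g_v"),
    ]
    scales = {
        "u": _simple_scale("u", [frozenset({"k_u"})], "g_u"),
        "v": _simple_scale("v", [frozenset({"k_v"})], "g_v"),
    }
    model = PLModel(variables, equations, scales, name="toggle-switch")
    spec = FixtureSpec(name=model.name, expected_steady_count=2)
    return model, spec


# ---------------------------------------------------------------------------
# random models
# ---------------------------------------------------------------------------

def _reachable_subsets_numeric(eq: Equation, var_intervals: dict[str, int],
                               thr_rank: dict[tuple[str, str], int]) -> set[frozenset[str]]:
    lit_vars = sorted({l.variable for t in eq.synthesis for l in t.literals})
    subsets = set()
    for combo in itertools.product(*(range(var_intervals[v]) for v in lit_vars)):
        lv = dict(zip(lit_vars, combo))
        active = []
        for term in eq.synthesis:
            ok = True
            for l in term.literals:
                above = lv[l.variable] > thr_rank[(l.variable, l.threshold)]
                if (above if l.sign == "+" else not above) is False:
                    ok = False
                    break
            if ok:
                active.append(term.rate)
        subsets.add(frozenset(active))
    return subsets


def random_model(
    n_vars: int,
    max_thresholds: int = 2,
    density: float = 0.5,
    seed: int = 0,
    allow_negative: bool = False,
) -> PLModel:
    """Seeded random PL model that always validates cleanly.

    Every variable gets a constitutive term; with probability ``density`` it
    also gets one AND-of-literals regulated term over other variables.  The
    landmark order is read off a concrete numeric draw, so it is a random
    order consistent with subset monotonicity and guaranteed realizable.
    """
    if n_vars < 1:
        raise ValueError("need n_vars >= 1")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)

    for _attempt in range(100):
        names = [f"x{i}" for i in range(1, n_vars + 1)]
        n_thr = {v: int(rng.integers(1, max_thresholds + 1)) for v in names}
        g = {v: float(np.exp(rng.uniform(np.log(0.1), np.log(10)))) for v in names}
        equations = []
        kval: dict[str, float] = {}
        for v in names:
            terms = [SynthesisTerm(f"k0_{v}")]
            kval[f"k0_{v}"] = float(np.exp(rng.uniform(np.log(0.1), np.log(10))))
            others = [u for u in names if u != v]
            if others and rng.random() < density:
                n_lits = int(rng.integers(1, min(2, len(others)) + 1))
                lit_vars = list(rng.choice(others, size=n_lits, replace=False))
                lits = []
                for u in lit_vars:
                    ti = int(rng.integers(0, n_thr[u]))
                    sign = "-" if (allow_negative and rng.random() < 0.5) else "+"
                    lits.append(StepLiteral(u, f"theta{ti + 1}_{u}", sign))
                terms.append(SynthesisTerm(f"k1_{v}", tuple(lits)))
                kval[f"k1_{v}"] = float(np.exp(rng.uniform(np.log(0.1), np.log(10))))
            equations.append(Equation(v, tuple(terms), f"g_{v}"))

        # numeric thresholds interleaved with the focal range of each variable
        thr_vals: dict[str, list[float]] = {}
        for v in names:
            top = sum(kval[r] for r in (f"k0_{v}", f"k1_{v}") if r in kval) / g[v]
            thr_vals[v] = sorted(float(x) for x in
                                 rng.uniform(0.0, 1.2 * top, size=n_thr[v]))
        thr_rank = {(v, f"theta{i + 1}_{v}"): i
                    for v in names for i in range(n_thr[v])}
        # threshold labels follow their numeric (ascending) order
        variables = [Variable(v, "state",
                              tuple(f"theta{i + 1}_{v}" for i in range(n_thr[v])))
                     for v in names]
        var_intervals = {v: n_thr[v] + 1 for v in names}

        scales = {}
        degenerate = False
        for v, eq in zip(names, equations):
            entries: list[tuple[float, Landmark]] = []
            for i in range(n_thr[v]):
                entries.append((thr_vals[v][i], threshold_landmark(f"theta{i + 1}_{v}")))
            for s in _reachable_subsets_numeric(eq, var_intervals, thr_rank):
                if s:
                    val = sum(kval[r] for r in s) / g[v]
                    entries.append((val, focal_landmark_symbol(s, f"g_{v}")))
            entries.sort(key=lambda e: e[0])
            vals = [e[0] for e in entries]
            if any(b - a < 1e-9 for a, b in zip(vals, vals[1:])) or \
               (vals and vals[0] < 1e-9):
                degenerate = True  # numeric tie: redraw everything
                break
            scales[v] = LandmarkScale(v, (ZERO, *(lm for _, lm in entries), MAX))
        if degenerate:
            continue

        model = PLModel(variables, equations, scales,
                        name=f"random-{n_vars}-seed{seed}")
        diags = validate_model(model)
        if not diags:
            return model
    raise RuntimeError("random model generation kept producing degenerate draws")
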
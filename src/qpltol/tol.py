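"""The minimized TOL network of *Pseudomonas putida* mt-2 as a PL model.

The TOL plasmid pWW0 encodes m-xylene catabolism through two operons (the
*upper* pathway, m-xylene -> 3-methylbenzoate, and the *meta* pathway,
3-methylbenzoate -> TCA intermediates) controlled by two transcription
factors, XylR and XylS.  The minimized model has four state variables with
one PL equation each and m-xylene as a clamped input:

    d(upper)/dt = k0_upper * s+(XylR, theta_XylR) * s+(m_xyl, theta_mxyl)
                  - g_upper * upper
    d(XylS)/dt  = k0_XylS + k1_XylS * s+(XylR, theta_XylR) * s+(m_xyl, theta_mxyl)
                  - g_XylS * XylS
    d(meta)/dt  = k0_meta * s+(XylS, theta2_XylSh)
                  + k1_meta * s+(XylS, theta1_XylSi) * s+(upper, theta_upper)
                            * s+(m_xyl, theta_mxyl)
                  - g_meta * meta
    d(XylR)/dt  = k0_XylR - g_XylR * XylR

3-methylbenzoate is not an explicit variable: XylS activation by the effector
is folded into the product of *upper* and m-xylene in the meta equation
(enzymatic turnover is fast relative to gene expression), and XylR
auto-repression is dropped because it merely keeps XylR supply constant.

In-silico mutants are pure reorderings of one landmark scale:

* ``no_xylsh`` — XylS hyper-expression cannot activate Pm: theta2_XylSh is
  placed above the maximal reachable XylS level (k0_XylS+k1_XylS)/g_XylS.
* ``no_xylsa`` — effector-activated XylS cannot form: the upper pathway
  never reaches the level theta_upper needed to supply 3-methylbenzoate,
  i.e. k0_upper/g_upper sits below theta_upper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

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
    active_terms,
    focal_landmark,
    focal_landmark_symbol,
    threshold_landmark,
    validate_model,
)
from .qsim import (
    StateTransitionGraph,
    build_stg,
    first_rise_position,
    shortest_path,
    steady_states,
    temporal_profiles,
)

GENOTYPES = ("wild_type", "no_xylsh", "no_xylsa")
MXYL_LEVELS = ("low", "high")


@dataclass(frozen=True)
class TOLCondition:
    """One simulation condition: a genotype (which inequality block to use)
    and the m-xylene clamp (below or above theta_mxyl)."""

    genotype: str = "wild_type"
    mxyl: str = "high"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.mxyl not in MXYL_LEVELS:
            raise ValueError(f"mxyl must be one of {MXYL_LEVELS}")


def _xyls_scale(genotype: str) -> LandmarkScale:
    th1 = threshold_landmark("theta1_XylSi")
    th2 = threshold_landmark("theta2_XylSh")
    f0 = focal_landmark_symbol({"k0_XylS"}, "g_XylS")
    f01 = focal_landmark_symbol({"k0_XylS", "k1_XylS"}, "g_XylS")
    if genotype == "no_xylsh":
        order = (ZERO, th1, f0, f01, th2, MAX)
    else:
        order = (ZERO, th1, f0, th2, f01, MAX)
    return LandmarkScale("XylS", order)


def _upper_scale(genotype: str) -> LandmarkScale:
    th = threshold_landmark("theta_upper")
    f = focal_landmark_symbol({"k0_upper"}, "g_upper")
    if genotype == "no_xylsa":
        order = (ZERO, f, th, MAX)
    else:
        order = (ZERO, th, f, MAX)
    return LandmarkScale("upper", order)


def build_tol_model(cond: TOLCondition | None = None, *,
                    genotype: str = "wild_type", mxyl: str = "high") -> PLModel:
    """Construct the minimized five-variable TOL model for one condition.

    Genotypes differ from the wild type only by the order of one landmark
    scale; the equations are identical in all three.
    """
    if cond is None:
        cond = TOLCondition(genotype=genotype, mxyl=mxyl)

    gate_xylr_mxyl = (
        StepLiteral("XylR", "theta_XylR", "+"),
        StepLiteral("m_xyl", "theta_mxyl", "+"),
    )
    # Declaration order fixes the lexicographic tie-break between equally
    # short paths; this order makes the highlighted path follow the known
    # activation itinerary (XylR first, upper and XylS before meta, XylS
    # hyper-expression completing last).
    variables = [
        Variable("XylS", "state", ("theta1_XylSi", "theta2_XylSh")),
        Variable("upper", "state", ("theta_upper",)),
        Variable("meta", "state", ("theta_meta",)),
        Variable("XylR", "state", ("theta_XylR",)),
        Variable("m_xyl", "input", ("theta_mxyl",)),
    ]
    equations = [
        Equation("upper",
                 (SynthesisTerm("k0_upper", gate_xylr_mxyl),),
                 "g_upper"),
        Equation("XylS",
                 (SynthesisTerm("k0_XylS"),
                  SynthesisTerm("k1_XylS", gate_xylr_mxyl)),
                 "g_XylS"),
        Equation("meta",
                 (SynthesisTerm("k0_meta",
                                (StepLiteral("XylS", "theta2_XylSh", "+"),)),
                  SynthesisTerm("k1_meta",
                                (StepLiteral("XylS", "theta1_XylSi", "+"),
                                 StepLiteral("upper", "theta_upper", "+"),
                                 StepLiteral("m_xyl", "theta_mxyl", "+")))),
                 "g_meta"),
        Equation("XylR",
                 (SynthesisTerm("k0_XylR"),),
                 "g_XylR"),
    ]
    scales = {
        "upper": _upper_scale(cond.genotype),
        "XylS": _xyls_scale(cond.genotype),
        "meta": LandmarkScale("meta", (
            ZERO,
            threshold_landmark("theta_meta"),
            focal_landmark_symbol({"k0_meta"}, "g_meta"),
            focal_landmark_symbol({"k1_meta"}, "g_meta"),
            focal_landmark_symbol({"k0_meta", "k1_meta"}, "g_meta"),
            MAX,
        )),
        "XylR": LandmarkScale("XylR", (
            ZERO,
            threshold_landmark("theta_XylR"),
            focal_landmark_symbol({"k0_XylR"}, "g_XylR"),
            MAX,
        )),
        "m_xyl": LandmarkScale("m_xyl", (
            ZERO, threshold_landmark("theta_mxyl"), MAX,
        )),
    }
    model = PLModel(
        variables=variables,
        equations=equations,
        scales=scales,
        clamps={"m_xyl": 1 if cond.mxyl == "high" else 0},
        name=f"tol-{cond.genotype.replace('_', '-')}-mxyl-{cond.mxyl}",
    )
    diags = validate_model(model)
    if diags:  # transcription bug, not a user error
        raise AssertionError(f"TOL model failed validation: {diags}")
    return model


# Qualitative steady-state levels stated for each condition: under low
# m-xylene only XylR is high and XylS sits at its basal level between its two
# thresholds; under induction all components reach their top relevant
# intervals, except that each mutant caps one of them.
EXPECTED_STEADY = {
    ("wild_type", "low"): {"upper": 0, "XylS": 1, "meta": 0, "XylR": 1},
    ("no_xylsh", "low"): {"upper": 0, "XylS": 1, "meta": 0, "XylR": 1},
    ("no_xylsa", "low"): {"upper": 0, "XylS": 1, "meta": 0, "XylR": 1},
    ("wild_type", "high"): {"upper": 1, "XylS": 2, "meta": 1, "XylR": 1},
    ("no_xylsh", "high"): {"upper": 1, "XylS": 1, "meta": 1, "XylR": 1},
    ("no_xylsa", "high"): {"upper": 0, "XylS": 2, "meta": 1, "XylR": 1},
}

# the two synthesis terms gated by active XylR (the single-input module)
SIM_TARGETS = (("upper", "k0_upper"), ("XylS", "k1_XylS"))


def term_active_in(model: PLModel, variable: str, rate: str,
                   state: QualitativeState) -> bool:
    """Whether the named synthesis term's literal conjunction holds in state."""
    return rate in active_terms(model.equation(variable), state, model)


def meta_rise_sources(model: PLModel, stg: StateTransitionGraph) -> list[QualitativeState]:
    """Source states of every STG edge along which meta's level increases."""
    return sorted(
        u for u, v in stg.graph.edges if v.level("meta") > u.level("meta")
    )


@dataclass
class SynchronyResult:
    """Outcome of a synchrony check between gated synthesis terms."""

    passed: bool
    first_active: dict[str, int | None]
    witness: QualitativeState | None
    path: list[QualitativeState]

    def __bool__(self) -> bool:
        return self.passed


def check_term_synchrony(
    model: PLModel,
    targets: Sequence[tuple[str, str]],
    initial: QualitativeState | None = None,
) -> SynchronyResult:
    """Check that several gated synthesis terms first become active in the
    same qualitative state along the deterministic shortest path to the
    unique steady state.

    ``targets`` is a sequence of (variable, rate) pairs.  The witness is the
    state where the earliest term switches on (for a pass, the common state).
    """
    stg = build_stg(model, initial)
    path = shortest_path(stg)
    if path is None:
        raise ValueError("steady state unreachable from the initial state")
    first: dict[str, int | None] = {}
    for variable, rate in targets:
        first[f"{variable}:{rate}"] = next(
            (i for i, s in enumerate(path)
             if term_active_in(model, variable, rate, s)),
            None,
        )
    indices = set(first.values())
    passed = len(indices) == 1 and None not in indices
    witness = None
    live = [i for i in first.values() if i is not None]
    if live:
        witness = path[min(live)]
    return SynchronyResult(passed=passed, first_active=first,
                           witness=witness, path=path)


def assert_sim_synchrony(cond: TOLCondition) -> SynchronyResult:
    """Verify the single-input-module synchrony: under induction, upper's
    synthesis term and XylS's XylR-gated term switch on in the same state
    (both are gated by the identical product
    s+(XylR, theta_XylR) * s+(m_xyl, theta_mxyl))."""
    if cond.mxyl != "high":
        raise ValueError("synchrony is defined under inducing conditions "
                         "(mxyl='high')")
    return check_term_synchrony(build_tol_model(cond), SIM_TARGETS)


@dataclass
class ScenarioReport:
    """Summary of one TOL simulation: STG size, steady-state levels, the
    deterministic shortest path, and the scenario's qualitative assertions.
    Assertions reference states by their level content, never by label."""

    condition: TOLCondition
    n_states: int
    n_transitions: int
    n_steady: int
    steady_levels: list[dict[str, int]]
    path_labels: list[str]
    profiles: pd.DataFrame
    meta_steady_focal: str | None
    meta_first_rise: int | None
    assertions: list[dict] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(a["passed"] for a in self.assertions)

    def to_dict(self) -> dict:
        return {
            "condition": {"genotype": self.condition.genotype,
                          "mxyl": self.condition.mxyl},
            "stg": {"n_states": self.n_states,
                    "n_transitions": self.n_transitions,
                    "n_steady": self.n_steady},
            "steady_levels": self.steady_levels,
            "shortest_path": self.path_labels,
            "meta_steady_focal": self.meta_steady_focal,
            "meta_first_rise": self.meta_first_rise,
            "assertions": self.assertions,
            "passed": self.passed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def run_scenario(cond: TOLCondition) -> ScenarioReport:
    """Build the model for one condition, run it from the all-zero state and
    evaluate the condition's qualitative assertions.  Assertion failures are
    reported, not raised."""
    model = build_tol_model(cond)
    stg = build_stg(model)
    steadies = sorted(steady_states(stg))
    assertions: list[dict] = []

    def check(name: str, passed: bool, detail: str) -> None:
        assertions.append({"name": name, "passed": bool(passed), "detail": detail})

    check("single_steady_state", len(steadies) == 1,
          f"found {len(steadies)} steady state(s)")

    path: list[QualitativeState] = []
    meta_focal_str = None
    meta_first = None
    if len(steadies) == 1:
        steady = steadies[0]
        expected = EXPECTED_STEADY[(cond.genotype, cond.mxyl)]
        observed = {k: steady.level(k) for k in expected}
        check("steady_levels", observed == expected,
              f"expected {expected}, observed {observed}")
        path = shortest_path(stg) or []
        meta_first = first_rise_position(path, "meta")
        lm = focal_landmark(model.equation("meta"), steady, model)
        meta_focal_str = lm.display()

        if cond.mxyl == "high":
            # meta may rise only once both XylR-gated terms are on (directly
            # reflects the meta equation's gating)
            sources = meta_rise_sources(model, stg)
            ok = all(
                term_active_in(model, "upper", "k0_upper", s)
                and term_active_in(model, "XylS", "k1_XylS", s)
                for s in sources
            ) if cond.genotype != "no_xylsa" else True
            if cond.genotype != "no_xylsa":
                check("meta_after_gated_terms", ok,
                      f"{len(sources)} meta-raising edge(s) inspected")
            if cond.genotype == "wild_type":
                sync = check_term_synchrony(model, SIM_TARGETS)
                check("sim_synchrony", sync.passed,
                      f"first activation indices {sync.first_active}")
        else:
            check("meta_silent", all(s.level("meta") == 0 for s in stg.graph.nodes),
                  "meta must stay at 0 without induction")

    return ScenarioReport(
        condition=cond,
        n_states=stg.n_states,
        n_transitions=stg.n_transitions,
        n_steady=len(steadies),
        steady_levels=[s.as_dict() for s in steadies],
        path_labels=[stg.label(s) for s in path],
        profiles=temporal_profiles(path),
        meta_steady_focal=meta_focal_str,
        meta_first_rise=meta_first,
        assertions=assertions,
    )


@dataclass
class MutantComparison:
    """meta's steady focal landmark per genotype under induction, with the
    order relations read off meta's landmark scale."""

    focal: dict[str, str]               # genotype -> landmark display
    scale_position: dict[str, int]      # genotype -> position on meta's scale
    above_theta_meta: dict[str, bool]
    meta_first_rise: dict[str, int | None]
    mutants_below_wild_type: bool
    timing_equal: bool

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "scale_position": self.scale_position,
            "above_theta_meta": self.above_theta_meta,
            "meta_first_rise": self.meta_first_rise,
            "mutants_below_wild_type": self.mutants_below_wild_type,
            "timing_equal": self.timing_equal,
        }


def compare_mutants() -> MutantComparison:
    """Rank meta's induced steady-state focal landmark across genotypes.

    The wild type converges to (k0_meta+k1_meta)/g_meta, the no-XylSh mutant
    to k1_meta/g_meta and the no-XylSa mutant to k0_meta/g_meta — both
    mutants strictly lower on meta's scale yet still above theta_meta, while
    the ordinal position of meta's first rise on the deterministic shortest
    path stays the same.
    """
    focal: dict[str, str] = {}
    pos: dict[str, int] = {}
    above: dict[str, bool] = {}
    rise: dict[str, int | None] = {}
    for genotype in GENOTYPES:
        cond = TOLCondition(genotype=genotype, mxyl="high")
        model = build_tol_model(cond)
        stg = build_stg(model)
        steadies = sorted(steady_states(stg))
        if len(steadies) != 1:
            raise AssertionError(f"{genotype}: expected a unique steady state")
        steady = steadies[0]
        scale = model.scale("meta")
        lm = focal_landmark(model.equation("meta"), steady, model)
        focal[genotype] = lm.display()
        pos[genotype] = scale.position(lm)
        theta_pos = scale.position(threshold_landmark("theta_meta"))
        above[genotype] = pos[genotype] > theta_pos
        path = shortest_path(stg) or []
        rise[genotype] = first_rise_position(path, "meta")
    mutants_below = (
        pos["no_xylsh"] < pos["wild_type"] and pos["no_xylsa"] < pos["wild_type"]
    )
    timing_equal = len({rise[g] for g in GENOTYPES}) == 1 and rise["wild_type"] is not None
    return MutantComparison(
        focal=focal,
        scale_position=pos,
        above_theta_meta=above,
        meta_first_rise=rise,
        mutants_below_wild_type=mutants_below,
        timing_equal=timing_equal,
    )
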
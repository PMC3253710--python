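"""Core data structures and semantics for piecewise-linear (PL) gene-network models.

A PL model describes each gene product ``x_i`` by an equation of the form

    dx_i/dt = sum_t k_t * prod(step literals of term t) - g_i * x_i

where every step literal ``s+(x_j, theta)`` (or ``s-``) is a Boolean indicator
that the concentration of ``x_j`` lies above (below) one of its thresholds.
Parameters are purely symbolic: instead of numbers, each variable carries a
*landmark scale*, a strict total order over ``zero``, its thresholds, the
focal ratios ``(sum of active k)/g`` reachable by some subset of its synthesis
terms, and ``max``.  Within a fixed arrangement of all variables relative to
their thresholds (a *regulatory domain*, here a :class:`QualitativeState`),
each variable converges monotonically toward the focal ratio of its currently
active synthesis terms, so the symbolic order alone determines the qualitative
dynamics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping


class ModelError(Exception):
    """Raised when a model is internally inconsistent (unknown symbol, missing
    landmark, literal referencing a foreign threshold, ...)."""


# ---------------------------------------------------------------------------
# symbols and terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variable:
    """A model component: a state variable (has one equation) or an input
    (clamped to a fixed interval, never changes)."""

    name: str
    role: str = "state"  # "state" | "input"
    thresholds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("state", "input"):
            raise ModelError(f"variable {self.name!r}: unknown role {self.role!r}")
        object.__setattr__(self, "thresholds", tuple(self.thresholds))

    @property
    def n_intervals(self) -> int:
        """k thresholds partition the axis into k+1 open intervals."""
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class StepLiteral:
    """``s+(variable, threshold)`` if sign is '+', ``s-`` if '-'.

    The threshold must belong to the literal's own variable.
    """

    variable: str
    threshold: str
    sign: str = "+"

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ModelError(f"step literal sign must be '+' or '-', got {self.sign!r}")


@dataclass(frozen=True)
class SynthesisTerm:
    """One additive synthesis term: a rate constant gated by the conjunction
    (product) of its step literals.  No literals = constitutive."""

    rate: str
    literals: tuple[StepLiteral, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "literals", tuple(self.literals))

    @property
    def is_constitutive(self) -> bool:
        return not self.literals


@dataclass(frozen=True)
class Equation:
    """dx/dt = sum(synthesis terms) - degradation_rate * x.

    Degradation is always present and linear in the variable, so every
    regulatory domain has a well-defined focal point.
    """

    variable: str
    synthesis: tuple[SynthesisTerm, ...] = ()
    degradation_rate: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "synthesis", tuple(self.synthesis))

    @property
    def rates(self) -> tuple[str, ...]:
        return tuple(t.rate for t in self.synthesis)


# ---------------------------------------------------------------------------
# landmarks and scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Landmark:
    """One symbol on a variable's axis.

    kind is one of ``zero``, ``threshold``, ``focal``, ``max``.  A focal
    landmark stands for the ratio ``(sum of rates)/degradation`` of one subset
    of the variable's synthesis terms; the subset is identified by the
    frozenset of rate symbols.
    """

    kind: str
    label: str | None = None                 # threshold landmarks only
    rates: frozenset[str] = frozenset()      # focal landmarks only
    degradation: str | None = None           # focal landmarks only

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "threshold", "focal", "max"):
            raise ModelError(f"unknown landmark kind {self.kind!r}")
        object.__setattr__(self, "rates", frozenset(self.rates))

    def display(self) -> str:
        if self.kind == "threshold":
            return self.label or "?"
        if self.kind == "focal":
            num = "+".join(sorted(self.rates))
            if len(self.rates) > 1:
                num = f"({num})"
            return f"{num}/{self.degradation}"
        return self.kind  # "zero" / "max"


ZERO = Landmark("zero")
MAX = Landmark("max")


def threshold_landmark(label: str) -> Landmark:
    return Landmark("threshold", label=label)


def focal_landmark_symbol(rates: Iterable[str], degradation: str) -> Landmark:
    return Landmark("focal", rates=frozenset(rates), degradation=degradation)


@dataclass(frozen=True)
class LandmarkScale:
    """Strict total order of one variable's landmarks, ``zero`` first and
    ``max`` last.  Substitutes for numeric parameter values: only the order
    matters for the qualitative dynamics."""

    variable: str
    landmarks: tuple[Landmark, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmarks", tuple(self.landmarks))

    def position(self, landmark: Landmark) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise ModelError(
                f"landmark {landmark.display()} not on the scale of {self.variable!r}"
            ) from None

    @property
    def thresholds(self) -> tuple[str, ...]:
        """Threshold labels in scale order."""
        return tuple(l.label for l in self.landmarks if l.kind == "threshold")

    def threshold_rank(self, label: str) -> int:
        """0-based rank of a threshold among this variable's thresholds."""
        try:
            return self.thresholds.index(label)
        except ValueError:
            raise ModelError(
                f"threshold {label!r} not on the scale of {self.variable!r}"
            ) from None

    def focal_landmark(self, rates: frozenset[str]) -> Landmark:
        """The landmark for the focal ratio of one active-term subset; the
        empty subset decays to zero."""
        if not rates:
            return self.landmarks[0]
        for l in self.landmarks:
            if l.kind == "focal" and l.rates == rates:
                return l
        raise ModelError(
            f"focal ratio for active set {sorted(rates)} missing from the "
            f"scale of {self.variable!r}"
        )

    def interval_of(self, landmark: Landmark) -> int:
        """Index of the threshold-bounded interval containing a (non-threshold)
        landmark: the number of thresholds strictly below it."""
        pos = self.position(landmark)
        return sum(
            1 for l in self.landmarks[:pos] if l.kind == "threshold"
        )


# ---------------------------------------------------------------------------
# qualitative states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualitativeState:
    """Assignment of every model variable to one threshold-bounded interval.

    Interval indices count from 0 (below the lowest threshold); a variable
    with k thresholds has intervals 0..k.  States are hashable and totally
    ordered (lexicographically on the level vector, in declared variable
    order) so graph nodes deduplicate and tie-breaks are deterministic.
    """

    names: tuple[str, ...]
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.names) != len(self.levels):
            raise ModelError("state names/levels length mismatch")

    def level(self, name: str) -> int:
        try:
            return self.levels[self.names.index(name)]
        except ValueError:
            raise ModelError(f"state does not cover variable {name!r}") from None

    def with_level(self, name: str, level: int) -> "QualitativeState":
        i = self.names.index(name)
        levels = self.levels[:i] + (level,) + self.levels[i + 1:]
        return QualitativeState(self.names, levels)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.levels))

    def __lt__(self, other: "QualitativeState") -> bool:
        return self.levels < other.levels

    def __le__(self, other: "QualitativeState") -> bool:
        return self.levels <= other.levels

    def __str__(self) -> str:
        return "(" + ", ".join(f"{n}={v}" for n, v in zip(self.names, self.levels)) + ")"


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class PLModel:
    """A complete symbolic PL system: variables, equations, one landmark scale
    per variable, and clamp levels for the inputs."""

    variables: list[Variable]
    equations: list[Equation]
    scales: dict[str, LandmarkScale]
    clamps: dict[str, int] = field(default_factory=dict)
    name: str = "pl-model"

    # -- lookups ----------------------------------------------------------
    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise ModelError(f"unknown variable {name!r}")

    def equation(self, name: str) -> Equation:
        for e in self.equations:
            if e.variable == name:
                return e
        raise ModelError(f"no equation for variable {name!r}")

    def scale(self, name: str) -> LandmarkScale:
        try:
            return self.scales[name]
        except KeyError:
            raise ModelError(f"no landmark scale for variable {name!r}") from None

    @property
    def state_variables(self) -> list[Variable]:
        return [v for v in self.variables if v.role == "state"]

    @property
    def input_variables(self) -> list[Variable]:
        return [v for v in self.variables if v.role == "input"]

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def make_state(self, levels: Mapping[str, int] | None = None) -> QualitativeState:
        """Build a state: inputs pinned at their clamps, state variables at 0
        unless overridden."""
        levels = dict(levels or {})
        out = []
        for v in self.variables:
            if v.role == "input":
                out.append(self.clamps.get(v.name, 0))
            else:
                out.append(levels.get(v.name, 0))
        return QualitativeState(self.variable_names, tuple(out))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PLModel):
            return NotImplemented
        return (
            self.variables == other.variables
            and self.equations == other.equations
            and self.scales == other.scales
            and self.clamps == other.clamps
            and self.name == other.name
        )


# ---------------------------------------------------------------------------
# evaluation within a qualitative state
# ---------------------------------------------------------------------------

def eval_step(literal: StepLiteral, state: QualitativeState, model: PLModel) -> int:
    """Evaluate one step literal in a qualitative state.

    A positive literal is 1 iff the variable's interval lies strictly above
    the threshold; a negative literal is the complement.
    """
    scale = model.scale(literal.variable)
    var = model.variable(literal.variable)
    if literal.threshold not in var.thresholds:
        raise ModelError(
            f"literal on {literal.variable!r} references threshold "
            f"{literal.threshold!r}, which is not one of its thresholds"
        )
    rank = scale.threshold_rank(literal.threshold)
    above = state.level(literal.variable) > rank
    if literal.sign == "+":
        return 1 if above else 0
    return 0 if above else 1


def active_terms(eq: Equation, state: QualitativeState, model: PLModel) -> frozenset[str]:
    """Rate symbols of the synthesis terms whose literal conjunctions all hold
    in ``state``.  Constitutive terms are always active."""
    active = []
    for term in eq.synthesis:
        if all(eval_step(l, state, model) for l in term.literals):
            active.append(term.rate)
    return frozenset(active)


def focal_landmark(eq: Equation, state: QualitativeState, model: PLModel) -> Landmark:
    """The landmark toward which the variable converges in ``state``: the
    focal ratio of its active terms, or ``zero`` under pure decay."""
    scale = model.scale(eq.variable)
    return scale.focal_landmark(active_terms(eq, state, model))


def focal_position(eq: Equation, state: QualitativeState, model: PLModel) -> int:
    """Index of the threshold-bounded interval containing the focal point of
    ``eq`` in ``state`` (0 = below the lowest threshold)."""
    scale = model.scale(eq.variable)
    return scale.interval_of(focal_landmark(eq, state, model))


# ---------------------------------------------------------------------------
# reachable active-term subsets
# ---------------------------------------------------------------------------

def reachable_term_subsets(model: PLModel, eq: Equation) -> set[frozenset[str]]:
    """All active-term subsets of an equation realizable by *some* arrangement
    of the literal variables relative to their thresholds.

    Inputs are allowed to range over all their intervals (not just the current
    clamp) so a single scale serves every simulation condition.
    """
    lit_vars = sorted({l.variable for t in eq.synthesis for l in t.literals})
    axes = []
    for name in lit_vars:
        axes.append(range(model.variable(name).n_intervals))
    subsets: set[frozenset[str]] = set()
    for combo in itertools.product(*axes):
        state = QualitativeState(tuple(lit_vars), combo)
        active = []
        for term in eq.synthesis:
            ok = True
            for l in term.literals:
                scale = model.scale(l.variable)
                above = state.level(l.variable) > scale.threshold_rank(l.threshold)
                bit = above if l.sign == "+" else not above
                if not bit:
                    ok = False
                    break
            if ok:
                active.append(term.rate)
        subsets.add(frozenset(active))
    return subsets


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: the violated invariant and the offending symbol."""

    code: str
    symbol: str
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.symbol}: {self.message}"


def validate_model(model: PLModel) -> list[Diagnostic]:
    """Check every structural invariant; returns an empty list iff the model
    is well-formed.  Diagnostics are returned, never raised."""
    diags: list[Diagnostic] = []

    def bad(code: str, symbol: str, message: str) -> None:
        diags.append(Diagnostic(code, symbol, message))

    # unique names, roles vs equations
    names = [v.name for v in model.variables]
    for n in sorted({n for n in names if names.count(n) > 1}):
        bad("duplicate-variable", n, "variable name declared more than once")
    eq_vars = [e.variable for e in model.equations]
    for v in model.variables:
        count = eq_vars.count(v.name)
        if v.role == "state" and count != 1:
            bad("equation-count", v.name,
                f"state variable must have exactly one equation, found {count}")
        if v.role == "input" and count != 0:
            bad("input-equation", v.name, "input variables must not have an equation")
    for ev in eq_vars:
        if ev not in names:
            bad("unknown-variable", ev, "equation for undeclared variable")

    # clamps
    for v in model.input_variables:
        if v.name not in model.clamps:
            bad("missing-clamp", v.name, "input variable has no clamp level")
        else:
            lvl = model.clamps[v.name]
            if not (0 <= lvl < v.n_intervals):
                bad("clamp-range", v.name,
                    f"clamp level {lvl} outside 0..{v.n_intervals - 1}")
    for n in model.clamps:
        if n not in names or model.variable(n).role != "input":
            bad("clamp-target", n, "clamp set on a non-input variable")

    # scales: structure and threshold housing
    for v in model.variables:
        if v.name not in model.scales:
            bad("missing-scale", v.name, "variable has no landmark scale")
            continue
        scale = model.scales[v.name]
        lms = scale.landmarks
        if scale.variable != v.name:
            bad("scale-owner", v.name, f"scale declares owner {scale.variable!r}")
        if not lms or lms[0].kind != "zero":
            bad("scale-extremes", v.name, "scale must start at zero")
        if not lms or lms[-1].kind != "max":
            bad("scale-extremes", v.name, "scale must end at max")
        if sum(1 for l in lms if l.kind == "zero") != 1 or \
           sum(1 for l in lms if l.kind == "max") != 1:
            bad("scale-extremes", v.name, "scale must have exactly one zero and one max")
        if len(set(lms)) != len(lms):
            seen: set[Landmark] = set()
            for l in lms:
                if l in seen:
                    bad("scale-tie", l.display(),
                        f"landmark appears twice on the scale of {v.name!r} "
                        "(the order must be strict)")
                seen.add(l)
        if scale.thresholds != v.thresholds:
            missing = set(v.thresholds) - set(scale.thresholds)
            extra = set(scale.thresholds) - set(v.thresholds)
            for t in sorted(missing):
                bad("threshold-housing", t,
                    f"threshold of {v.name!r} missing from its scale")
            for t in sorted(extra):
                bad("threshold-housing", t,
                    f"scale of {v.name!r} houses a threshold the variable "
                    "does not declare")
            if not missing and not extra:
                bad("threshold-order", v.name,
                    "scale threshold order disagrees with the declared order")

    # literals: ownership and existence
    for e in model.equations:
        for t in e.synthesis:
            for l in t.literals:
                if l.variable not in names:
                    bad("literal-variable", l.variable,
                        f"literal in equation for {e.variable!r} references an "
                        "undeclared variable")
                    continue
                owner = model.variable(l.variable)
                if l.threshold not in owner.thresholds:
                    bad("literal-threshold", l.threshold,
                        f"literal on {l.variable!r} uses a threshold that does "
                        "not belong to it")

    # focal landmarks: rate housing, degradation consistency, reachable
    # subsets present, subset monotonicity
    for e in model.equations:
        if e.variable not in model.scales or e.variable not in names:
            continue
        scale = model.scales[e.variable]
        rates = e.rates
        if len(set(rates)) != len(rates):
            bad("duplicate-rate", e.variable,
                "synthesis terms must carry distinct rate symbols")
            continue
        focals = [l for l in scale.landmarks if l.kind == "focal"]
        for f in focals:
            if not f.rates <= set(rates):
                bad("focal-rates", f.display(),
                    f"focal landmark of {e.variable!r} references rates not in "
                    "its equation")
            if f.degradation != e.degradation_rate:
                bad("focal-degradation", f.display(),
                    f"focal landmark of {e.variable!r} must use its "
                    f"degradation rate {e.degradation_rate!r}")
        if any(d.code in ("literal-variable", "literal-threshold", "missing-scale",
                          "threshold-housing")
               for d in diags):
            continue  # subset reachability needs consistent literals/scales
        try:
            reachable = reachable_term_subsets(model, e)
        except ModelError:
            continue
        housed = {f.rates for f in focals}
        for s in sorted(reachable, key=sorted):
            if s and s not in housed:
                bad("missing-focal", "+".join(sorted(s)),
                    f"reachable active-term subset of {e.variable!r} has no "
                    "focal landmark on the scale")
        for a, b in itertools.combinations(focals, 2):
            lo, hi = (a, b) if a.rates < b.rates else (b, a)
            if lo.rates < hi.rates and scale.position(lo) > scale.position(hi):
                bad("focal-monotonicity", hi.display(),
                    f"adding synthesis terms must not move the focal ratio of "
                    f"{e.variable!r} downward (violates {lo.display()} < "
                    f"{hi.display()})")

    # input scales carry no focal landmarks
    for v in model.input_variables:
        scale = model.scales.get(v.name)
        if scale and any(l.kind == "focal" for l in scale.landmarks):
            bad("input-focal", v.name,
                "input variables have no equation and hence no focal landmarks")

    return diags
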
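"""Numerical certification of the qualitative engine.

The symbolic analysis never touches numbers; this module closes the loop.
It draws concrete parameter values consistent with a model's landmark orders,
integrates the PL system exactly — within one regulatory domain each variable
follows

    x_i(t) = phi_i + (x_i(0) - phi_i) * exp(-g_i t),

with ``phi_i = (sum of active k)/g_i`` the focal value, so threshold-crossing
times have the closed form ``t* = (1/g) ln((x0 - phi)/(theta - phi))`` — and
checks that the discretized trajectory is a path of the state transition
graph ending in one of its steady states.

Sampling is deterministic per seed and per-variable: degradation rates are
drawn log-uniformly, synthesis rates are redrawn until the induced numeric
order of the reachable focal ratios matches the symbolic scale (per-variable
rejection; the scale orders shipped with this package are all realizable),
and thresholds/max are then interpolated between the numeric focal anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    Landmark,
    ModelError,
    PLModel,
    QualitativeState,
    active_terms,
)
from .qsim import StateTransitionGraph

#: absolute tolerance for treating a concentration as sitting on a threshold
EVENT_TOL = 1e-9


class SamplingError(ModelError):
    """No numeric instantiation of a variable's scale was found."""


@dataclass(frozen=True)
class ParameterSample:
    """Concrete numbers for every landmark and rate symbol of a model.

    ``values`` maps threshold labels, rate symbols (k's), degradation symbols
    (g's) and per-variable ``max_<var>`` keys to floats; zero is implicitly 0.
    The values satisfy every strict order relation of every landmark scale.
    """

    values: dict[str, float]
    seed: int

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def landmark_value(self, model: PLModel, variable: str, lm: Landmark) -> float:
        if lm.kind == "zero":
            return 0.0
        if lm.kind == "max":
            return self.values[f"max_{variable}"]
        if lm.kind == "threshold":
            return self.values[lm.label]
        g = self.values[lm.degradation]
        return sum(self.values[r] for r in lm.rates) / g


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def sample_parameters(model: PLModel, seed: int, max_tries: int = 10000) -> ParameterSample:
    """Draw one concrete parameter set consistent with every landmark scale.

    Deterministic given ``seed``.  Variables are processed in declared order;
    each variable's k's are rejection-sampled until the numeric order of its
    reachable focal ratios matches its scale, after which thresholds and max
    are placed by sorted-uniform interpolation between the focal anchors.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for v in model.variables:
        scale = model.scale(v.name)
        lms = scale.landmarks
        focals = [l for l in lms if l.kind == "focal"]
        if v.role == "state":
            eq = model.equation(v.name)
            g = float(_loguniform(rng, 0.1, 10.0))
            values[eq.degradation_rate] = g
            ks: dict[str, float] = {}
            if focals:
                for _ in range(max_tries):
                    trial = {r: float(_loguniform(rng, 0.1, 10.0))
                             for r in eq.rates}
                    fv = [sum(trial[r] for r in f.rates) / g for f in focals]
                    if all(a < b - EVENT_TOL for a, b in zip(fv, fv[1:])):
                        ks = trial
                        break
                else:
                    raise SamplingError(
                        f"could not realize the focal order of {v.name!r} in "
                        f"{max_tries} tries"
                    )
            values.update(ks)
        # anchors: numeric values already fixed (zero and focal ratios); walk
        # the scale and interpolate threshold runs between consecutive anchors
        anchor_vals: list[float | None] = []
        for lm in lms:
            if lm.kind == "zero":
                anchor_vals.append(0.0)
            elif lm.kind == "focal":
                g = values[lm.degradation]
                anchor_vals.append(sum(values[r] for r in lm.rates) / g)
            else:
                anchor_vals.append(None)  # threshold or max: to be placed
        i = 0
        while i < len(lms):
            if anchor_vals[i] is not None:
                i += 1
                continue
            j = i
            while j < len(lms) and anchor_vals[j] is None:
                j += 1
            lo = anchor_vals[i - 1]
            if j < len(lms):
                hi = anchor_vals[j]
                run = j - i
            else:
                # trailing run ends at max: extend beyond the last anchor
                run = len(lms) - i
                hi = lo + max(lo, 1.0) * (run + 1)
            u = np.sort(rng.uniform(0.05, 0.95, size=run))
            for r in range(run):
                anchor_vals[i + r] = lo + (hi - lo) * float(u[r])
            if j == len(lms):
                anchor_vals[-1] = hi  # max itself
            i = j
        # register threshold and max values
        for lm, val in zip(lms, anchor_vals):
            if lm.kind == "threshold":
                values[lm.label] = float(val)
            elif lm.kind == "max":
                values[f"max_{v.name}"] = float(val)
        # audit: the numeric order must reproduce the symbolic order exactly
        seq = [values[lm.label] if lm.kind == "threshold"
               else val for lm, val in zip(lms, anchor_vals)]
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise SamplingError(f"sampled values violate the scale of {v.name!r}")
    return ParameterSample(values=values, seed=seed)


# ---------------------------------------------------------------------------
# event-driven integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One inter-event stretch inside a single regulatory domain."""

    t0: float
    t1: float
    x0: tuple[float, ...]       # state-variable concentrations at t0
    focal: tuple[float, ...]    # focal values in this domain
    g: tuple[float, ...]
    levels: tuple[int, ...]     # qualitative interval per state variable

    def x_at(self, t: float) -> np.ndarray:
        dt = t - self.t0
        x0 = np.asarray(self.x0)
        phi = np.asarray(self.focal)
        return phi + (x0 - phi) * np.exp(-np.asarray(self.g) * dt)


@dataclass
class Trajectory:
    """A concrete solution path: exponential segments between threshold
    crossings, plus the terminal flag."""

    variables: tuple[str, ...]          # state-variable names
    segments: list[Segment]
    terminal: str                       # "converged" | "t_end" | "sliding_detected"
    sample: ParameterSample
    model_name: str = ""

    @property
    def times(self) -> list[float]:
        return [s.t0 for s in self.segments] + [self.segments[-1].t1]

    def x_at(self, t: float) -> np.ndarray:
        for seg in self.segments:
            if seg.t0 <= t <= seg.t1:
                return seg.x_at(t)
        raise ValueError(f"time {t} outside the trajectory")

    @property
    def final(self) -> np.ndarray:
        last = self.segments[-1]
        return last.x_at(last.t1)


def _domain_state(model: PLModel, levels: dict[str, int]) -> QualitativeState:
    return model.make_state(levels)


def integrate_pl(
    model: PLModel,
    sample: ParameterSample,
    x0: dict[str, float] | None = None,
    t_end: float = 100.0,
) -> Trajectory:
    """Integrate the PL system event-to-event with closed-form segments.

    ``x0`` maps state-variable names to nonnegative initial concentrations
    (default all zero).  Integration stops when the flow converges inside a
    domain (``converged``), when ``t_end`` is reached, or when a crossing
    immediately pushes back across the same threshold from the other side
    (``sliding_detected``).
    """
    svars = [v.name for v in model.state_variables]
    x = np.array([(x0 or {}).get(n, 0.0) for n in svars], dtype=float)
    if np.any(x < 0):
        raise ValueError("initial concentrations must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    # qualitative levels of the state variables, maintained exactly
    levels = {}
    for n, xi in zip(svars, x):
        ths = [sample[t] for t in model.variable(n).thresholds]
        levels[n] = sum(1 for th in ths if xi > th)

    g = np.array([sample[model.equation(n).degradation_rate] for n in svars])
    segments: list[Segment] = []
    t = 0.0
    terminal = "t_end"

    while True:
        state = _domain_state(model, levels)
        phi = np.empty(len(svars))
        for i, n in enumerate(svars):
            eq = model.equation(n)
            act = active_terms(eq, state, model)
            phi[i] = sum(sample[r] for r in act) / g[i]

        # earliest threshold crossing toward the focal value, per variable
        t_cross = np.inf
        cross_var = -1
        cross_thr = 0.0
        cross_dir = 0
        for i, n in enumerate(svars):
            if abs(phi[i] - x[i]) <= EVENT_TOL:
                continue
            d = 1 if phi[i] > x[i] else -1
            candidates = [
                sample[lab] for lab in model.variable(n).thresholds
                if (d > 0 and x[i] + EVENT_TOL < sample[lab] < phi[i] - EVENT_TOL)
                or (d < 0 and phi[i] + EVENT_TOL < sample[lab] < x[i] - EVENT_TOL)
            ]
            if not candidates:
                continue
            theta = min(candidates) if d > 0 else max(candidates)
            ts = math.log((x[i] - phi[i]) / (theta - phi[i])) / g[i]
            if ts < t_cross:
                t_cross, cross_var, cross_thr, cross_dir = ts, i, theta, d

        if not math.isfinite(t_cross):
            # no variable will cross again: converge inside this domain
            segments.append(Segment(t, t_end, tuple(x), tuple(phi), tuple(g),
                                    tuple(levels[n] for n in svars)))
            terminal = "converged"
            break
        if t + t_cross >= t_end:
            segments.append(Segment(t, t_end, tuple(x), tuple(phi), tuple(g),
                                    tuple(levels[n] for n in svars)))
            terminal = "t_end"
            break

        segments.append(Segment(t, t + t_cross, tuple(x), tuple(phi), tuple(g),
                                tuple(levels[n] for n in svars)))
        x = phi + (x - phi) * np.exp(-g * t_cross)
        x[cross_var] = cross_thr  # land exactly on the threshold
        t += t_cross
        name = svars[cross_var]
        levels[name] += cross_dir

        # sliding check: does the new domain push straight back?
        new_state = _domain_state(model, levels)
        eq = model.equation(name)
        act = active_terms(eq, new_state, model)
        new_phi = sum(sample[r] for r in act) / g[cross_var]
        if (new_phi - cross_thr) * cross_dir < -EVENT_TOL:
            terminal = "sliding_detected"
            segments.append(Segment(t, t, tuple(x),
                                    tuple(phi), tuple(g),
                                    tuple(levels[n] for n in svars)))
            break

    return Trajectory(variables=tuple(svars), segments=segments,
                      terminal=terminal, sample=sample, model_name=model.name)


# ---------------------------------------------------------------------------
# discretization and soundness
# ---------------------------------------------------------------------------

def qualitative_state_at(
    model: PLModel, sample: ParameterSample, x: np.ndarray,
    variables: tuple[str, ...],
) -> QualitativeState:
    """Classify a concentration vector into its regulatory domain.  A value
    within EVENT_TOL of a threshold is rejected (measure-zero; resample)."""
    levels = {}
    for n, xi in zip(variables, x):
        ths = [sample[t] for t in model.variable(n).thresholds]
        for th in ths:
            if abs(xi - th) <= EVENT_TOL:
                raise SamplingError(
                    f"concentration of {n!r} sits on a threshold; resample"
                )
        levels[n] = sum(1 for th in ths if xi > th)
    return model.make_state(levels)


def discretize(traj: Trajectory, model: PLModel) -> list[QualitativeState]:
    """Map each inter-event segment to its regulatory domain (classified at
    an interior point of the segment); consecutive duplicates collapse."""
    if traj.terminal == "sliding_detected":
        raise ValueError("cannot discretize a trajectory that hit a sliding mode")
    out: list[QualitativeState] = []
    for seg in traj.segments:
        if seg.t1 > seg.t0:
            mid = seg.x_at(seg.t0 + 0.5 * (seg.t1 - seg.t0))
        else:
            mid = np.asarray(seg.x0)
        state = qualitative_state_at(model, traj.sample, mid, traj.variables)
        if not out or state != out[-1]:
            out.append(state)
    return out


@dataclass(frozen=True)
class SoundnessResult:
    passed: bool
    violation: tuple[QualitativeState, QualitativeState] | None = None

    def __bool__(self) -> bool:
        return self.passed


def check_soundness(
    stg: StateTransitionGraph, qual_sequence: list[QualitativeState]
) -> SoundnessResult:
    """Pass iff every consecutive pair of the discretized sequence is an STG
    edge (or the states are equal); on failure names the first missing edge."""
    for a, b in zip(qual_sequence, qual_sequence[1:]):
        if a != b and not stg.graph.has_edge(a, b):
            return SoundnessResult(False, (a, b))
    return SoundnessResult(True)


def audit_model(
    model: PLModel,
    stg: StateTransitionGraph,
    n_seeds: int = 50,
    t_end: float = 200.0,
    base_seed: int = 0,
) -> "pd.DataFrame":
    """Headline certification loop: for ``n_seeds`` parameter samples,
    integrate from the all-zero state, discretize, and check (a) that the
    sequence is an STG path, (b) that a converged trajectory ends in an STG
    steady state whose landmark intervals contain the numeric terminal value.
    """
    import pandas as pd

    rows = []
    steadies = stg.steady
    for i in range(n_seeds):
        seed = base_seed + i
        sample = sample_parameters(model, seed)
        traj = integrate_pl(model, sample, t_end=t_end)
        row = {"seed": seed, "terminal": traj.terminal,
               "sound": False, "steady_ok": False}
        if traj.terminal != "sliding_detected":
            seq = discretize(traj, model)
            row["sound"] = bool(check_soundness(stg, seq))
            if traj.terminal == "converged":
                term = qualitative_state_at(model, sample, traj.final,
                                            traj.variables)
                row["steady_ok"] = term in steadies and term == seq[-1]
        rows.append(row)
    return pd.DataFrame(rows)
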
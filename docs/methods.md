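# Methods

## Piecewise-linear models with symbolic inequalities

A model is a set of variables (state or clamped input), one equation per
state variable, and one landmark scale per variable.  An equation is a sum
of synthesis terms — a rate symbol `k` gated by the conjunction of step
literals `s±(x, θ)` — minus linear degradation `g·x`.  Within a fixed
arrangement of all variables relative to their thresholds (a *regulatory
domain*), the right-hand side is affine and each variable relaxes
exponentially toward its *focal value* `φ = (Σ active k)/g`.

Numbers are replaced by order: each variable's landmark scale is a strict
total order over `zero`, its thresholds, the focal ratios of its reachable
active-term subsets, and `max`.  Strictness is enforced at validation (a tie
would make the qualitative dynamics ill-defined).  The scale must house the
focal ratio of every *reachable* active-term subset — subsets that no
arrangement of the literal variables can activate (e.g. a regulated term
without its constitutive companion) need no landmark.  Subset monotonicity
is an invariant: `S ⊂ S'` forces `ratio(S)` before `ratio(S')`, so adding
synthesis can never lower a focal position.  Negative literals are fully
supported even though the packaged TOL model uses none (its XylR
auto-repression is folded away); the toggle-switch fixture exercises them.

Inputs occupy the interval chosen by their clamp and never move.

## Qualitative simulation

The simulator operates on regulatory domains only (boundary/switching
domains are out of scope): a successor moves exactly one variable one
interval toward its current focal interval (asynchronous unit steps).  For
strict inequality chains and the monotone circuits studied here this
abstraction agrees with richer PL semantics on reachability, steady states
and event ordering; the numerical oracle certifies exactly that, which is
why the simpler semantics is safe for these models.  Breadth-first closure
from the initial state (all state variables at interval 0 by default — a
naive, uninduced cell) yields the STG; steady states are the nodes with no
outgoing edge.  Damped approach to a focal point inside a domain cannot
oscillate in this abstraction, so out-degree 0 is the complete criterion.

State labels `s1, s2, …` follow breadth-first discovery order and carry no
meaning; positions along a path are ordinal (consecutive conditions, not
clock time).

**Shortest-path tie-break.**  Several equally short paths usually exist; for
reproducible output the engine always takes, among successors lying on a
shortest path, the lexicographically smallest state in declared variable
order.  The highlighted path is therefore a display convention, not a
dynamical claim — every ordering assertion in the package is either checked
over all edges/states of the STG or explicitly tied to this deterministic
path.  The TOL model declares its variables in the order
`XylS, upper, meta, XylR, m_xyl`, chosen so that the highlighted induced
path follows the biologically known activation itinerary (XylR first, upper
and XylS next, *meta* after both, hyper-expression completing last); the
STG, its steady states and all term-activation results are independent of
declaration order.

## The TOL instance

Equations and inequality chains are as printed in the package sources
(`qpltol/tol.py`): upper and XylS are AND-gated by active XylR and
m-xylene, XylS additionally has a weak constitutive term, *meta* is an OR of
a hyper-expressed-XylS branch (`θ²_XylSh`) and an effector branch (XylS
above `θ¹_XylSi` AND upper AND m-xylene — 3-methylbenzoate is not an
explicit variable: enzymatic conversion is fast relative to expression, so
the effector is represented by the conjunction of its producers), and XylR
is constitutive.  The genotypes differ only in one scale order:
`no_xylsh` places `θ²_XylSh` above the maximal reachable XylS level;
`no_xylsa` places `θ_upper` above `k⁰_upper/g_upper`.  m-xylene `high/low`
clamp above/below `θ_mxyl`; the input has a single threshold, no
intermediate levels.  The "timing unchanged" mutant result is
operationalized as equality, across genotypes, of the ordinal position of
*meta*'s first rise on the deterministic shortest path — qualitative states
carry no clock, so path position is the only available notion of timing.

## Numerical certification

`sample_parameters` draws, per variable: `g` log-uniform on [0.1, 10];
synthesis rates log-uniform on [0.1, 10], redrawn (rejection) until the
numeric order of the reachable focal ratios matches the symbolic scale —
per-variable rejection keeps acceptance fast, and every shipped or generated
scale is realizable by construction; thresholds and `max` are then placed by
sorted-uniform interpolation between the numeric focal anchors (trailing
landmarks extend beyond the last anchor).  Rejection rather than
back-solving is used because focal ratios are additive in the `k`'s while
landmark placements are free, so prescribing positions for all subset sums
is overdetermined.  Everything is deterministic given the seed.

Integration is event-driven and exact: inside a domain
`x(t) = φ + (x₀ − φ)e^(−gt)`, and the next event is the minimum over
variables of the closed-form crossing time
`t* = (1/g)·ln((x₀ − φ)/(θ − φ))` over thresholds lying strictly between
the current value and the focal value.  The crossing variable is landed
exactly on the threshold and its qualitative interval updated discretely,
so classification never depends on floating-point comparisons at the
boundary.  If the new domain's flow immediately pushes back across the same
threshold the run terminates as `sliding_detected` (Filippov resolution is
out of scope; no monotone fixture in the package can slide).  A value within
`1e-9` (absolute) of a threshold during discretization is rejected as
degenerate — a measure-zero event under continuous sampling.

Discretization classifies an interior point of each inter-event segment
against the sampled thresholds and collapses duplicates; soundness holds iff
every consecutive pair is an STG edge.  The audit additionally requires a
converged run to end in an STG steady state whose landmark intervals contain
the numeric endpoint.  Cross-validation against a generic stiff integrator
(LSODA on the same discontinuous vector field) agrees to better than 1e-6
relative at the endpoint on the TOL and toggle fixtures.

## Synthetic fixtures

The generators emulate the structural assumptions of the analysis — strict
total landmark orders, monotone AND-gated activation cascades, optional
negative feedback — with known expected behavior (`FixtureSpec`):
cascades have a unique all-high steady state with strict stage order on
every path; the toggle switch is bistable from the symmetric off-state; the
single-input fan-out reproduces synchronous target activation.
`random_model` draws a random topology (a constitutive term per variable
plus, with probability `density`, one AND-of-literals regulated term over
other variables, thresholds 1..`max_thresholds`) and **derives the symbolic
scale from a concrete numeric draw**, guaranteeing that every emitted order
is additively realizable (arbitrary linear extensions of the subset-sum
lattice need not be) and that the oracle can always instantiate it.
Degenerate draws (numeric ties) are redrawn; generation is seeded and
deterministic.

What the fixtures do *not* emulate: measured kinetics, transcriptional
noise, growth-phase effects, host factors, or unmodeled intermediate
metabolites — passing tests certify the symbolic engine and its numerical
abstraction, not quantitative behavior of real promoters.

## Problem sizes and defaults

The packaged analyses are small by nature (the TOL state space has 24
qualitative states per clamp).  Default audit sizes — 50 parameter samples
per scenario, 100 random 3-variable fixture models, `t_end = 200` with
`g ≥ 0.1` so every transient has fully decayed — were chosen as generous
for circuits of this size while keeping any run interactive (seconds).

## Known limitations

* No switching-domain (boundary) states: behavior that exists only on
  thresholds (sliding modes) is detected and reported, not analyzed.
* Steady states are sinks of the unit-step STG; limit cycles appear as
  cycles without sinks, not as oscillatory "attractors" with a period.
* The model format covers step-function PL systems only — no Hill
  functions, no stochastic kinetics, no parameter estimation from data.
* Timing statements are ordinal; the framework cannot rank genotypes by
  real response time.
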
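"""Generate synthetic PL circuits and verify their expected behavior.

A toggle switch (negative literals, bistable), an activation cascade
(ordered monotone chain) and seeded random monotone models.
"""

from qpltol.qsim import build_stg, steady_states
from qpltol.synth import make_cascade, make_toggle_switch, random_model, \
    verify_fixture
from qpltol.model import validate_model

toggle, toggle_spec = make_toggle_switch()
res = verify_fixture(toggle, toggle_spec)
print(f"toggle switch: {res['n_steady']} steady states from the off-state "
      f"(expected {toggle_spec.expected_steady_count})")

cascade, spec = make_cascade(4)
res = verify_fixture(cascade, spec)
print(f"cascade of 4: unique steady state={res['steady_count_ok']}, "
      f"stage order respected on every path: {res['ordering_ok']}")

n_single = 0
for seed in range(25):
    model = random_model(3, max_thresholds=2, density=0.7, seed=seed)
    assert validate_model(model) == []
    n_single += len(steady_states(build_stg(model))) == 1
print(f"random monotone models: {n_single}/25 have exactly one steady state")
# Monotone (activation-only) networks funnel into a single attractor from
# the all-zero state; bistability requires repression, as in the toggle.
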
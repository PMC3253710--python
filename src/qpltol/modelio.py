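"""Reading and writing PL models as structured text (YAML).

The format mirrors the in-memory structure: ``variables``, ``equations``
(terms as a rate plus a list of step-literal strings), ``scales`` (ordered
landmark-symbol lists) and ``clamps``.  Step literals are written
``s+(var, threshold)`` / ``s-(var, threshold)``; focal-ratio landmarks are
written ``k/g`` or ``(k1+k2)/g`` with the rate symbols in sorted order, which
makes the serialization canonical: read -> write -> read is the identity.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml

from .model import (
    MAX,
    ZERO,
    Equation,
    Landmark,
    LandmarkScale,
    ModelError,
    PLModel,
    StepLiteral,
    SynthesisTerm,
    Variable,
    focal_landmark_symbol,
    threshold_landmark,
)

_LITERAL_RE = re.compile(r"^s([+-])\(\s*([^,\s]+)\s*,\s*([^)\s]+)\s*\)$")


def literal_to_str(lit: StepLiteral) -> str:
    return f"s{lit.sign}({lit.variable}, {lit.threshold})"


def literal_from_str(text: str) -> StepLiteral:
    m = _LITERAL_RE.match(text.strip())
    if not m:
        raise ModelError(f"cannot parse step literal {text!r}")
    sign, var, thr = m.groups()
    return StepLiteral(variable=var, threshold=thr, sign=sign)


def landmark_to_str(lm: Landmark) -> str:
    return lm.display()


def landmark_from_str(text: str, variable: str, model_thresholds: set[str]) -> Landmark:
    text = text.strip()
    if text == "zero":
        return ZERO
    if text == "max":
        return MAX
    if "/" in text:
        num, _, den = text.rpartition("/")
        num = num.strip()
        if num.startswith("(") and num.endswith(")"):
            num = num[1:-1]
        rates = [r.strip() for r in num.split("+") if r.strip()]
        if not rates or not den.strip():
            raise ModelError(f"cannot parse focal landmark {text!r}")
        return focal_landmark_symbol(rates, den.strip())
    return threshold_landmark(text)


def model_to_dict(model: PLModel) -> dict:
    return {
        "name": model.name,
        "variables": [
            {"name": v.name, "role": v.role, "thresholds": list(v.thresholds)}
            for v in model.variables
        ],
        "equations": [
            {
                "variable": e.variable,
                "degradation": e.degradation_rate,
                "synthesis": [
                    {"rate": t.rate, "literals": [literal_to_str(l) for l in t.literals]}
                    for t in e.synthesis
                ],
            }
            for e in model.equations
        ],
        "scales": {
            name: [landmark_to_str(l) for l in scale.landmarks]
            for name, scale in model.scales.items()
        },
        "clamps": dict(model.clamps),
    }


def model_from_dict(data: dict) -> PLModel:
    if not isinstance(data, dict) or "variables" not in data:
        raise ModelError("model file is missing the 'variables' section")
    variables = [
        Variable(
            name=v["name"],
            role=v.get("role", "state"),
            thresholds=tuple(v.get("thresholds", ())),
        )
        for v in data["variables"]
    ]
    all_thresholds = {t for v in variables for t in v.thresholds}
    equations = [
        Equation(
            variable=e["variable"],
            degradation_rate=e["degradation"],
            synthesis=tuple(
                SynthesisTerm(
                    rate=t["rate"],
                    literals=tuple(literal_from_str(s) for s in t.get("literals", ())),
                )
                for t in e.get("synthesis", ())
            ),
        )
        for e in data.get("equations", ())
    ]
    scales = {
        name: LandmarkScale(
            variable=name,
            landmarks=tuple(
                landmark_from_str(s, name, all_thresholds) for s in entries
            ),
        )
        for name, entries in data.get("scales", {}).items()
    }
    return PLModel(
        variables=variables,
        equations=equations,
        scales=scales,
        clamps={k: int(v) for k, v in (data.get("clamps") or {}).items()},
        name=data.get("name", "pl-model"),
    )


def dumps_model(model: PLModel) -> str:
    return yaml.safe_dump(model_to_dict(model), sort_keys=False)


def loads_model(text: str) -> PLModel:
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ModelError(f"model file is not valid YAML: {exc}") from exc
    if data is None:
        raise ModelError("model file is empty")
    return model_from_dict(data)


def write_model(model: PLModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model))


def read_model(path: str | Path) -> PLModel:
    return loads_model(Path(path).read_text())
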
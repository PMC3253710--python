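import pytest

from qpltol.tol import TOLCondition, build_tol_model


@pytest.fixture(scope="session")
def tol_wt_high():
    return build_tol_model(TOLCondition("wild_type", "high"))


@pytest.fixture(scope="session")
def tol_wt_low():
    return build_tol_model(TOLCondition("wild_type", "low"))


@pytest.fixture(scope="session")
def tol_models():
    return {
        (g, m): build_tol_model(TOLCondition(g, m))
        for g in ("wild_type", "no_xylsh", "no_xylsa")
        for m in ("low", "high")
    }
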
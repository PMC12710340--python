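import pytest

from rrescout import fixtures as fx
from rrescout import structmodel as sm


@pytest.fixture(scope="session")
def spec():
    return fx.FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def fold_panel(spec):
    """(name, structure, truth) triples for the idealized fold panel."""
    return fx.fold_panel_structures(spec)


@pytest.fixture(scope="session")
def panel_classifications(fold_panel):
    """name -> (truth, RREClassification) for the whole panel."""
    out = {}
    for name, structure, truth in fold_panel:
        ss = sm.assign_secondary_structure(structure, "A")
        out[name] = (truth, sm.detect_rre_fold(ss))
    return out
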
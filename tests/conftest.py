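import numpy as np
import pytest

from xlcui.synthetic import GenConfig, build_lexicon, generate_corpus, generate_terminology
from xlcui.terminology import Concept, Terminology


@pytest.fixture(scope="session")
def ambiguity_terminology() -> Terminology:
    """Two PROC concepts with near-synonym surface forms but distinct CUIs."""
    return Terminology([
        Concept("C0013516", "PROC", [("ENG", "echocardiography", True)]),
        Concept("C1655737", "PROC", [("ENG", "cardiac ultrasound", True)]),
    ])


@pytest.fixture(scope="session")
def history_terminology() -> Terminology:
    return Terminology([
        Concept("C0455533", "DISO", [("ENG", "H/O: thromboembolism", True)]),
        Concept("C1997787", "DISO", [("ENG", "history of thromboembolism", True)]),
    ])


@pytest.fixture(scope="session")
def small_world():
    """A small deterministic synthetic world shared across tests."""
    cfg = GenConfig(docs=12, seed=5)
    term = generate_terminology(cfg)
    docs = generate_corpus(term, cfg)
    return cfg, term, docs, build_lexicon(term)
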
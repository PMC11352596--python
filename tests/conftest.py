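import numpy as np
import pytest

from gazelink.embedding import HashNgramBackend
from gazelink.kb_io import GazetteerEntry, MentionAnnotation


@pytest.fixture(scope="session")
def backend():
    return HashNgramBackend(dim=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_gazetteer():
    return [
        GazetteerEntry("38341003", "hipertensión", "finding", "es", True),
        GazetteerEntry("38341003", "tensión alta", "finding", "es", False),
        GazetteerEntry("25064002", "dolor de cabeza", "finding", "es", True),
        GazetteerEntry("22253000", "dolor", "finding", "es", True),
    ]


def make_mention(code="25064002", text="dolor de cabeza", start=10, label="SINTOMA", doc="doc1"):
    return MentionAnnotation(
        doc_id=doc, start=start, end=start + len(text), text=text, label=label, codes=(code,)
    )


@pytest.fixture()
def coded_mentions():
    return [
        make_mention("25064002", "dolor de cabeza", 10),
        make_mention("38341003", "tensión alta", 40),
    ]
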
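import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from levensong.corpus import PhraseString, Singer, SongCorpus
from levensong.units import CostMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_singer(singer_id: str, phrases: list[tuple[str, str]]) -> Singer:
    """Build a singer from (phrase_type, 'a b c') pairs."""
    s = Singer(singer_id=singer_id)
    for ptype, units in phrases:
        s.phrases.append(PhraseString(units=tuple(units.split()), phrase_type=ptype))
    return s


def make_corpus(*singers: Singer) -> SongCorpus:
    c = SongCorpus()
    for s in singers:
        c.add(s)
    return c


@pytest.fixture
def tiny_corpus() -> SongCorpus:
    """Two locations, three singers, two themes."""
    return make_corpus(
        make_singer("NC01S1", [("1A", "a b c"), ("1A", "a b c"), ("2A", "d e")]),
        make_singer("NC02S1", [("1A", "a b c"), ("2A", "d e f")]),
        make_singer("TO01S1", [("1B", "a x c"), ("2A", "d e")]),
    )


@pytest.fixture
def small_costs() -> CostMatrix:
    labels = ("a", "b", "c", "d", "e", "f", "x")
    n = len(labels)
    rng = np.random.default_rng(7)
    m = rng.uniform(0.1, 1.0, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return CostMatrix(labels=labels, costs=m)
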
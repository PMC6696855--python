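import pytest

from sbdh_screen.lexicon import compile_matcher, default_lexicon
from sbdh_screen.synthetic import SimulationConfig, generate_annotation_fixture, generate_ehr


@pytest.fixture(scope="session")
def lexicon_set():
    return default_lexicon()


@pytest.fixture(scope="session")
def matcher(lexicon_set):
    return compile_matcher(lexicon_set)


@pytest.fixture(scope="session")
def small_ehr(lexicon_set):
    """A 2,000-patient synthetic EHR shared by read-only tests."""
    return generate_ehr(SimulationConfig(n_patients=2000, seed=11), lexicon_set)


@pytest.fixture(scope="session")
def annotation_fixture():
    return generate_annotation_fixture(seed=3)


def naive_phrase_scan(text: str, phrases: list[str]) -> list[tuple[int, int, str]]:
    """Brute-force oracle: lowercase scan testing every phrase at every
    position with alphanumeric word-boundary checks."""
    low = text.lower()
    hits = []
    for phrase in phrases:
        p = phrase.lower()
        for i in range(len(low) - len(p) + 1):
            if low[i : i + len(p)] != p:
                continue
            before_ok = i == 0 or not low[i - 1].isalnum()
            j = i + len(p)
            after_ok = j == len(low) or not low[j].isalnum()
            if before_ok and after_ok:
                hits.append((i, j, phrase))
    return sorted(hits)
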
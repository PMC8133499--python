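import pytest

from pianodbh import CohortSpec, build_hanon_score, build_scale_score, generate_cohort
from pianodbh.pipeline import builtin_scores


@pytest.fixture(scope="session")
def scores():
    return builtin_scores()


@pytest.fixture(scope="session")
def hanon_small():
    """Two-pattern ascending-only Hanon for fast note-level checks."""
    return build_hanon_score(n_patterns=2, include_descending=False)


@pytest.fixture(scope="session")
def scale_one_octave():
    return build_scale_score(octaves=1)


@pytest.fixture(scope="session")
def small_cohort(scores):
    """4 experts + 4 amateurs on both excerpts, fixed seed."""
    spec = CohortSpec(n_expert=4, n_amateur=4, seed=7)
    return generate_cohort(spec, scores)
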
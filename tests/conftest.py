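import itertools

import pytest

from semacd.scoring import COLON_SEGMENTS, NOT_ASSESSED, SemaRating
from semacd.synthetic_data import GeneratorConfig, generate_study


def enumerate_valid_ratings(video_id="v", reader_id="r", include_na=True):
    """Every valid SEMA-CD rating state (up to segment identity).

    Ileum in 0..4 (plus NOT_ASSESSED), colon grade 0..4, and every involved
    set consistent with the colon grade.
    """
    ileum_values = list(range(5)) + ([NOT_ASSESSED] if include_na else [])
    for ileum in ileum_values:
        for colon in range(5):
            if colon == 0:
                seg_sets = [frozenset()]
            else:
                seg_sets = [
                    frozenset(c)
                    for k in range(1, 5)
                    for c in itertools.combinations(COLON_SEGMENTS, k)
                ]
            for segs in seg_sets:
                yield SemaRating(
                    video_id=video_id,
                    reader_id=reader_id,
                    ileum=ileum,
                    colon_overall=colon,
                    involved_segments=segs,
                )


def rating_with_total(total, video_id="v", reader_id="r", occasion="primary_1"):
    """A fully assessed rating whose SEMA-CD total equals ``total`` (0-20)."""
    for ileum in range(5):
        for colon in range(5):
            for k in range(5):
                if (colon == 0) != (k == 0):
                    continue
                if ileum + colon * k == total:
                    segs = frozenset(COLON_SEGMENTS[:k])
                    return SemaRating(video_id=video_id, reader_id=reader_id,
                                      occasion=occasion, ileum=ileum,
                                      colon_overall=colon, involved_segments=segs)
    raise ValueError(f"no rating with total {total}")


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=42, n_patients=30)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    return generate_study(GeneratorConfig(seed=7))
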
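import pytest
from hypothesis import settings

from cfa import Corpus, Post, SynthConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_post(post_id, body, user_id="u1", subforum="bipolar", title=""):
    return Post(post_id, user_id, subforum, "2019-01-01T00:00:00Z", title, body)


@pytest.fixture
def tiny_corpus():
    return Corpus(
        [
            make_post("p1", "I was recovering well and recovered fully.", user_id="u1"),
            make_post("p2", "Taking care of myself helps with hope.", user_id="u2"),
            make_post("p3", "Nothing relevant here at all today.", user_id="u2"),
        ],
        name="tiny",
    )


@pytest.fixture(scope="session")
def synth():
    """One shared default-condition synthetic corpus with ground truth."""
    return generate(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def synth_small():
    """A small, fast corpus for oracle recounts."""
    return generate(
        SynthConfig(seed=11, n_users=20, posts_per_user=(2, 5), words_per_post=(20, 60))
    )
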
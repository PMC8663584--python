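import pytest

from plm import (SynonymGroup, SyntheticSpec, TopicLink, TrainingConfig,
                 generate_corpus, train)

PLANTED_GROUPS = {
    "breathlessness": ["breathlessness", "gasping", "wheezy"],
    "cough": ["cough", "coughing", "hacking"],
    "mucus": ["sputum", "phlegm", "muck"],
}


def planted_spec(seed: int = 7, n_posts: int = 800) -> SyntheticSpec:
    """Small corpus (~110k tokens) with three planted symptom synonym groups."""
    groups = [SynonymGroup(name, members, 0.35)
              for name, members in PLANTED_GROUPS.items()]
    return SyntheticSpec(
        n_posts=n_posts, post_length_mean=140, post_length_dispersion=5,
        background_vocab_size=800,
        synonym_groups=groups,
        topic_links=[TopicLink("breathlessness", "mucus", 0.1)],
        misspelling_rate=0.02, rng_seed=seed)


@pytest.fixture(scope="session")
def planted_corpus():
    corpus, truth = generate_corpus(planted_spec())
    return corpus, truth


@pytest.fixture(scope="session")
def planted_model(planted_corpus):
    """One trained model shared by the embedding / lexicon / salience tests."""
    corpus, _ = planted_corpus
    cfg = TrainingConfig(dimension=50, epochs=5, min_count=3, rng_seed=13)
    return train(corpus, cfg)
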
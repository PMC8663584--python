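"""Synthetic patient-post corpora with planted semantic ground truth.

The original scraped forum corpus is not redistributable, so every
downstream stage is exercised on generated text whose structure is known:

* a Zipf-distributed background vocabulary (natural-language-like skew, so
  frequent-word subsampling and the unigram^0.75 noise distribution are
  exercised nontrivially);
* planted synonym groups whose members are drawn interchangeably from a
  shared within-group unigram distribution — members therefore occupy
  interchangeable contexts and an embedding should place them near each
  other;
* per-post Bernoulli group activation with optional pairwise topic links
  that force two groups to co-occur in the same post at a controlled rate;
* optional misspelling variant tokens that belong to the same group.

Defaults mirror the kind of corpus the analysis is meant for: several
thousand posts averaging ~190 tokens, i.e. on the order of a million words.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, Post

_VOWELS = "aeiou"


@dataclass
class SynonymGroup:
    """A named set of interchangeable terms with a per-post activation share."""

    name: str
    members: list[str]
    share: float


@dataclass
class TopicLink:
    """Pairwise forcing: with probability ``probability`` both groups are
    activated in a post, on top of their independent activations."""

    group_a: str
    group_b: str
    probability: float


@dataclass
class SyntheticSpec:
    n_posts: int = 5663
    post_length_mean: float = 190.0
    post_length_dispersion: float = 5.0  # negative-binomial shape; larger = tighter
    background_vocab_size: int = 2000
    zipf_exponent: float = 1.0
    synonym_groups: list[SynonymGroup] = field(default_factory=list)
    topic_links: list[TopicLink] = field(default_factory=list)
    misspelling_rate: float = 0.0
    group_token_rate: float = 0.2  # fraction of post tokens drawn from active groups
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_posts < 1:
            raise ValueError("n_posts must be >= 1")
        if self.post_length_mean < 5:
            raise ValueError("post_length_mean must be >= 5")
        if self.post_length_dispersion <= 0:
            raise ValueError("post_length_dispersion must be > 0")
        if self.background_vocab_size < 1:
            raise ValueError("background_vocab_size must be >= 1")
        if not 0.0 <= self.misspelling_rate <= 1.0:
            raise ValueError("misspelling_rate must be in [0, 1]")
        if not 0.0 < self.group_token_rate <= 1.0:
            raise ValueError("group_token_rate must be in (0, 1]")
        names = [g.name for g in self.synonym_groups]
        if len(set(names)) != len(names):
            raise ValueError("synonym_groups: duplicate group names")
        seen_terms: set[str] = set()
        share_sum = 0.0
        for g in self.synonym_groups:
            if len(g.members) < 2:
                raise ValueError(
                    f"synonym_groups[{g.name}]: every group needs >= 2 members")
            if not 0.0 <= g.share <= 1.0:
                raise ValueError(f"synonym_groups[{g.name}]: share must be in [0, 1]")
            overlap = seen_terms.intersection(g.members)
            if overlap or len(set(g.members)) != len(g.members):
                raise ValueError(
                    f"synonym_groups[{g.name}]: member terms must be disjoint")
            seen_terms.update(g.members)
            share_sum += g.share
        for link in self.topic_links:
            if not 0.0 <= link.probability <= 1.0:
                raise ValueError(
                    f"topic_links[{link.group_a},{link.group_b}]: "
                    "probability must be in [0, 1]")
            for nm in (link.group_a, link.group_b):
                if nm not in names:
                    raise ValueError(f"topic_links: unknown group {nm!r}")

    def to_dict(self) -> dict:
        return {
            "n_posts": self.n_posts,
            "post_length_mean": self.post_length_mean,
            "post_length_dispersion": self.post_length_dispersion,
            "background_vocab_size": self.background_vocab_size,
            "zipf_exponent": self.zipf_exponent,
            "synonym_groups": [
                {"name": g.name, "members": list(g.members), "share": g.share}
                for g in self.synonym_groups],
            "topic_links": [
                {"group_a": l.group_a, "group_b": l.group_b,
                 "probability": l.probability} for l in self.topic_links],
            "misspelling_rate": self.misspelling_rate,
            "group_token_rate": self.group_token_rate,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        d = dict(d)
        d["synonym_groups"] = [SynonymGroup(**g) for g in d.get("synonym_groups", [])]
        d["topic_links"] = [TopicLink(**l) for l in d.get("topic_links", [])]
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class GroundTruth:
    """What was planted: term->group map, per-post active groups, and the
    expected post-level co-occurrence count for each topic link."""

    term_to_group: dict[str, str]
    post_groups: dict[str, set[str]]
    expected_cooccurrence: dict[tuple[str, str], float]

    def members_of(self, group: str) -> list[str]:
        return sorted(t for t, g in self.term_to_group.items() if g == group)

    def realized_cooccurrence(self, group_a: str, group_b: str) -> int:
        """Posts in which both groups were activated (exact, by construction)."""
        return sum(1 for gs in self.post_groups.values()
                   if group_a in gs and group_b in gs)


def misspell(term: str) -> str:
    """Deterministic misspelling variant of a term (vowel drop / doubling)."""
    for i in range(1, len(term) - 1):
        if term[i] in _VOWELS:
            return term[:i] + term[i + 1:]
    return term + term[-1]


def _background_vocab(size: int) -> list[str]:
    return [f"word{i:04d}" for i in range(size)]


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a tokenized corpus plus its ground truth, reproducibly.

    Per post: group activations are sampled (independent Bernoulli at each
    group's share, then pairwise links force co-activation), then each token
    slot is filled from an active group with probability ``group_token_rate``
    (group chosen uniformly among active, member from the within-group
    distribution, misspelled at ``misspelling_rate``) and from the Zipf
    background otherwise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    bg_vocab = _background_vocab(spec.background_vocab_size)
    ranks = np.arange(1, spec.background_vocab_size + 1, dtype=float)
    bg_probs = ranks ** -spec.zipf_exponent
    bg_probs /= bg_probs.sum()
    bg_cdf = np.cumsum(bg_probs)

    groups = spec.synonym_groups
    term_to_group: dict[str, str] = {}
    member_cdfs: list[np.ndarray] = []
    variants: list[list[str]] = []
    for g in groups:
        # Within-group unigram distribution: harmonic weights, first member
        # (the canonical term) most frequent.
        w = 1.0 / np.arange(1, len(g.members) + 1)
        member_cdfs.append(np.cumsum(w / w.sum()))
        var_list = []
        for m in g.members:
            term_to_group[m] = g.name
            v = misspell(m)
            if v in term_to_group and term_to_group[v] != g.name:
                v = m + "x"
            var_list.append(v)
            if spec.misspelling_rate > 0:
                term_to_group[v] = g.name
        variants.append(var_list)

    # Expected post-level co-occurrence under the activation model:
    # P(both) = p_link + (1 - p_link) * share_a * share_b.
    expected: dict[tuple[str, str], float] = {}
    share = {g.name: g.share for g in groups}
    for link in spec.topic_links:
        p_both = link.probability + (1.0 - link.probability) * \
            share[link.group_a] * share[link.group_b]
        expected[(link.group_a, link.group_b)] = spec.n_posts * p_both

    nb_r = spec.post_length_dispersion
    nb_p = nb_r / (nb_r + spec.post_length_mean)

    base_date = np.datetime64("2016-02-01")
    posts: list[Post] = []
    post_groups: dict[str, set[str]] = {}
    for i in range(spec.n_posts):
        pid = f"post-{i:06d}"
        active = {g.name for g in groups if rng.random() < g.share}
        for link in spec.topic_links:
            if rng.random() < link.probability:
                active.add(link.group_a)
                active.add(link.group_b)
        post_groups[pid] = active
        active_idx = [j for j, g in enumerate(groups) if g.name in active]

        length = max(5, int(rng.negative_binomial(nb_r, nb_p)))
        tokens: list[str] = []
        u_slot = rng.random(length)
        for u in u_slot:
            if active_idx and u < spec.group_token_rate:
                j = active_idx[int(rng.integers(len(active_idx)))]
                m = int(np.searchsorted(member_cdfs[j], rng.random()))
                if spec.misspelling_rate > 0 and rng.random() < spec.misspelling_rate:
                    tokens.append(variants[j][m])
                else:
                    tokens.append(groups[j].members[m])
            else:
                tokens.append(bg_vocab[int(np.searchsorted(bg_cdf, rng.random()))])
        date = str(base_date + int(rng.integers(0, 1280)))
        posts.append(Post(id=pid, source="synthetic", date=date,
                          raw_text=" ".join(tokens), tokens=tokens))

    truth = GroundTruth(term_to_group=term_to_group, post_groups=post_groups,
                        expected_cooccurrence=expected)
    return Corpus(posts), truth


def make_fixture_with_counts(
    total_posts: int,
    hits_per_lexicon: Mapping[str, int],
    rng_seed: int = 0,
    terms_per_lexicon: Mapping[str, Sequence[str]] | None = None,
    disjoint: bool = False,
    filler_vocab_size: int = 50,
    post_length: int = 20,
) -> tuple[Corpus, dict[str, set[str]]]:
    """Build a corpus in which exactly ``hits_per_lexicon[name]`` posts
    contain >= 1 term of each named lexicon.

    Hit sets are sampled without replacement; overlaps between lexicons are
    allowed unless ``disjoint``.  Returns the corpus and the planted post-id
    hit set per lexicon.  Enables exact reproduction of printed mention
    fractions such as 413/3938.
    """
    if total_posts < 1:
        raise ValueError("total_posts must be >= 1")
    for name, k in hits_per_lexicon.items():
        if not 0 <= k <= total_posts:
            raise ValueError(
                f"hit count for {name!r} ({k}) exceeds total_posts ({total_posts})")
    if disjoint and sum(hits_per_lexicon.values()) > total_posts:
        raise ValueError("disjoint hit counts exceed total_posts")

    rng = np.random.default_rng(rng_seed)
    terms = {name: list(terms_per_lexicon[name]) if terms_per_lexicon else [name]
             for name in hits_per_lexicon}
    filler = _background_vocab(filler_vocab_size)
    lex_terms_flat = {t for ts in terms.values() for t in ts}

    ids = [f"post-{i:06d}" for i in range(total_posts)]
    hit_sets: dict[str, set[str]] = {}
    available = list(range(total_posts))
    for name in sorted(hits_per_lexicon):
        k = hits_per_lexicon[name]
        if disjoint:
            pick = rng.choice(len(available), size=k, replace=False)
            chosen = [available[j] for j in sorted(pick, reverse=True)]
            for j in sorted(pick, reverse=True):
                available.pop(j)
        else:
            chosen = list(rng.choice(total_posts, size=k, replace=False))
        hit_sets[name] = {ids[j] for j in chosen}

    posts = []
    for i, pid in enumerate(ids):
        toks = [filler[int(rng.integers(len(filler)))] for _ in range(post_length)]
        # filler vocab never collides with lexicon terms; guard anyway
        toks = [t for t in toks if t not in lex_terms_flat] or [filler[0]]
        for name in sorted(hit_sets):
            if pid in hit_sets[name]:
                pos = int(rng.integers(len(toks) + 1))
                toks.insert(pos, terms[name][int(rng.integers(len(terms[name])))])
        posts.append(Post(id=pid, source="fixture", raw_text=" ".join(toks),
                          tokens=toks))
    return Corpus(posts), hit_sets


def context_count_vectors(corpus: Corpus, window: int = 5
                          ) -> tuple[dict[str, int], np.ndarray]:
    """Empirical context-count matrix by symmetric window scan.

    Used to verify, before any embedding is trained, that planted synonym
    group members have more similar context distributions to each other than
    to background words.
    """
    vocab: dict[str, int] = {}
    for toks in corpus.token_sequences():
        for t in toks:
            if t not in vocab:
                vocab[t] = len(vocab)
    mat = np.zeros((len(vocab), len(vocab)), dtype=np.float64)
    for toks in corpus.token_sequences():
        idx = [vocab[t] for t in toks]
        for i, ci in enumerate(idx):
            lo = max(0, i - window)
            hi = min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    mat[ci, idx[j]] += 1.0
    return vocab, mat
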
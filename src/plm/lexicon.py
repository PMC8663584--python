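"""Seed-lexicon expansion by embedding-neighbor search, with curation hooks.

A lexicon starts from a few canonical clinical seed terms (e.g.
breathlessness / cough / sputum for symptoms; anxiety, depression, fatigue,
pain, exercise for impacts) and is expanded with the community words and
phrases whose embedding vectors lie near a seed by cosine similarity.
Human review is modeled as explicit accept/reject lists so the procedure is
systematic and repeatable rather than ad hoc.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus
from .sgns import EmbeddingModel, nearest_neighbors
from .text import PHRASE_JOINER

log = logging.getLogger(__name__)

STATUS_AUTO = "auto"
STATUS_ACCEPTED = "accepted"
STATUS_REJECTED = "rejected"


@dataclass
class LexiconTerm:
    token: str
    similarity: float | None  # cosine to the best-matching probe; None if curated in
    provenance: str | None    # the seed term this expansion traces back to
    status: str = STATUS_AUTO


@dataclass
class Lexicon:
    """Seed terms plus expanded community terms with curation status."""

    name: str
    seeds: list[str]
    terms: list[LexiconTerm] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._check()

    def _check(self) -> None:
        active = {t.token for t in self.terms}
        both = (set(self.rejected) & active) | (set(self.rejected) & set(self.seeds))
        if both:
            raise ValueError(f"lexicon {self.name!r}: tokens both active and "
                             f"rejected: {sorted(both)}")

    @property
    def active_terms(self) -> list[str]:
        """Seeds plus non-rejected expanded/curated terms, deduplicated."""
        out = list(self.seeds)
        seen = set(self.seeds)
        for t in self.terms:
            if t.token not in seen:
                out.append(t.token)
                seen.add(t.token)
        return out

    def term(self, token: str) -> LexiconTerm | None:
        for t in self.terms:
            if t.token == token:
                return t
        return None

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"name": self.name, "seeds": list(self.seeds),
                "terms": [{"token": t.token, "similarity": t.similarity,
                           "provenance": t.provenance, "status": t.status}
                          for t in self.terms],
                "rejected": list(self.rejected)}

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        return cls(name=d["name"], seeds=list(d["seeds"]),
                   terms=[LexiconTerm(**t) for t in d["terms"]],
                   rejected=list(d["rejected"]))

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def expand(model: EmbeddingModel, seeds: list[str], k_per_seed: int = 25,
           min_similarity: float = 0.4, rounds: int = 1,
           name: str = "lexicon") -> Lexicon:
    """Expand seed terms into a lexicon via top-k cosine neighbors.

    Out-of-vocabulary seeds are reported and skipped; it is an error only if
    none remain.  With ``rounds > 1`` the terms found in round r become
    probes in round r+1; each term is recorded once with its maximum
    similarity and the root seed it traces back to.  Deterministic given the
    model.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if k_per_seed < 1:
        raise ValueError("k_per_seed must be >= 1")
    in_vocab = [s for s in seeds if s in model.vocab]
    missing = [s for s in seeds if s not in model.vocab]
    if missing:
        log.warning("lexicon %s: seeds not in vocabulary: %s", name, missing)
    if not in_vocab:
        raise KeyError(f"lexicon {name!r}: no seed term is in the vocabulary")

    found: dict[str, LexiconTerm] = {}
    probes: list[tuple[str, str]] = [(s, s) for s in in_vocab]  # (probe, root seed)
    seed_set = set(seeds)
    for _ in range(rounds):
        new_probes: list[tuple[str, str]] = []
        for probe, root in probes:
            for tok, sim in nearest_neighbors(model, probe, k_per_seed):
                if sim < min_similarity or tok in seed_set:
                    continue
                prev = found.get(tok)
                if prev is None:
                    found[tok] = LexiconTerm(tok, sim, root, STATUS_AUTO)
                    new_probes.append((tok, root))
                elif sim > prev.similarity:
                    prev.similarity = sim
                    prev.provenance = root
        probes = new_probes
        if not probes:
            break
    terms = sorted(found.values(), key=lambda t: (-t.similarity, t.token))
    return Lexicon(name=name, seeds=list(seeds), terms=terms)


def apply_curation(lex: Lexicon, accept: list[str] | None = None,
                   reject: list[str] | None = None) -> Lexicon:
    """Apply accept/reject lists, returning a new lexicon.

    Rejected tokens leave the active set and are recorded; accepted tokens
    are flagged (added with no similarity if they were never proposed).
    Seeds cannot be rejected.
    """
    accept = list(accept or [])
    reject = list(reject or [])
    overlap = set(accept) & set(reject)
    if overlap:
        raise ValueError(f"tokens in both accept and reject: {sorted(overlap)}")
    bad = set(reject) & set(lex.seeds)
    if bad:
        raise ValueError(f"cannot reject seed terms: {sorted(bad)}")

    terms: list[LexiconTerm] = []
    for t in lex.terms:
        if t.token in reject:
            continue
        status = STATUS_ACCEPTED if t.token in accept else t.status
        terms.append(LexiconTerm(t.token, t.similarity, t.provenance, status))
    present = {t.token for t in terms} | set(lex.seeds)
    for tok in accept:
        if tok not in present:
            terms.append(LexiconTerm(tok, None, None, STATUS_ACCEPTED))
    rejected = sorted(set(lex.rejected) | set(reject))
    return Lexicon(name=lex.name, seeds=list(lex.seeds), terms=terms,
                   rejected=rejected)


def excerpt_sampler(corpus: Corpus, lex: Lexicon, n: int,
                    context_window_chars: int = 80, rng_seed: int = 0
                    ) -> list[tuple[str, str, str]]:
    """Uniformly sample up to ``n`` mention excerpts for human review.

    Returns (post id, term, excerpt) triples; the excerpt is the raw text
    around the matched term (phrase tokens are looked up with the joiner
    replaced by a space).  Reproducible under the seed; empty if the lexicon
    never matches.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    active = set(lex.active_terms)
    mentions: list[tuple[str, str, str]] = []
    for post in corpus:
        toks = post.tokens if post.tokens is not None else []
        hit_terms = sorted({t for t in toks if t in active})
        for term in hit_terms:
            surface = term.replace(PHRASE_JOINER, " ")
            pos = post.raw_text.casefold().find(surface)
            if pos >= 0:
                lo = max(0, pos - context_window_chars)
                hi = min(len(post.raw_text),
                         pos + len(surface) + context_window_chars)
                excerpt = post.raw_text[lo:hi]
            else:
                i = toks.index(term)
                excerpt = " ".join(toks[max(0, i - 10):i + 11])
            mentions.append((post.id, term, excerpt))
    if not mentions:
        return []
    rng = np.random.default_rng(rng_seed)
    if n >= len(mentions):
        return mentions
    pick = rng.choice(len(mentions), size=n, replace=False)
    return [mentions[i] for i in sorted(pick)]


def save_lexicons_tsv(lexicons: list[Lexicon], path: str | Path) -> None:
    """Flat two-column (token, lexicon) export for interoperability."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("token\tlexicon\n")
        for lex in lexicons:
            for tok in lex.active_terms:
                fh.write(f"{tok}\t{lex.name}\n")
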
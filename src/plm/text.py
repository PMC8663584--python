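"""Tokenization and collocation (phrase) merging.

Patients write multi-word expressions — ``pursed-lip``, ``difficulty
exercising`` — that must become single vocabulary items before embedding
training, otherwise no vector exists for the phrase.  Tokenization keeps
word-internal hyphens and apostrophes; phrase detection uses the count-ratio
collocation score

    score(a, b) = (count(ab) - delta) * N / (count(a) * count(b))

with ``N`` the corpus token count and ``delta`` a discount that suppresses
rare accidental bigrams.  Adjacent bigrams scoring above a threshold are
joined with ``_``; a second pass lets trigram phrases form.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field

from .corpus import Corpus, Post

# Word-internal hyphens/apostrophes stay inside a token; underscore is
# reserved as the phrase joiner and never appears in raw tokens.
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’\-][^\W_]+)*", re.UNICODE)

PHRASE_JOINER = "_"


def tokenize(raw_text: str) -> list[str]:
    """Lowercase, NFC-normalize and split ``raw_text`` into word tokens.

    Punctuation other than word-internal hyphens/apostrophes is stripped.
    Total on strings: empty input yields an empty list.
    """
    text = unicodedata.normalize("NFC", raw_text).casefold()
    return _TOKEN_RE.findall(text)


def tokenize_corpus(corpus: Corpus) -> Corpus:
    """Return a new corpus with ``tokens`` filled in for every post."""
    return Corpus([Post(p.id, p.source, p.date, p.raw_text, tokenize(p.raw_text))
                   for p in corpus])


@dataclass
class PhraseTable:
    """Collocation scores for adjacent bigrams above a count floor."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float = 10.0
    discount: float = 5.0
    min_count: int = 5
    passes: int = 2

    def score(self, a: str, b: str) -> float:
        return self.scores.get((a, b), 0.0)


def score_bigrams(corpus: Corpus, min_count: int = 5,
                  discount: float = 5.0) -> PhraseTable:
    """Score every adjacent within-post bigram occurring >= ``min_count`` times.

    Scores are clamped at zero (a bigram count equal to the discount scores
    exactly 0).  An empty corpus yields an empty table.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if discount < 0:
        raise ValueError("discount must be >= 0")
    unigram: Counter[str] = Counter()
    bigram: Counter[tuple[str, str]] = Counter()
    for toks in corpus.token_sequences():
        unigram.update(toks)
        bigram.update(zip(toks, toks[1:]))
    n_tokens = sum(unigram.values())
    scores: dict[tuple[str, str], float] = {}
    for (a, b), nab in bigram.items():
        if nab < min_count:
            continue
        scores[(a, b)] = max(0.0, (nab - discount)) * n_tokens / (
            unigram[a] * unigram[b])
    return PhraseTable(scores=scores, discount=discount, min_count=min_count)


def _merge_once(tokens: list[str], table: PhraseTable, threshold: float) -> list[str]:
    # Greedy left-to-right, non-overlapping within one pass.
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and table.score(tokens[i], tokens[i + 1]) > threshold:
            out.append(tokens[i] + PHRASE_JOINER + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def merge_phrases(corpus: Corpus, table: PhraseTable,
                  threshold: float | None = None,
                  passes: int | None = None) -> Corpus:
    """Join high-scoring adjacent bigrams into single ``_``-joined tokens.

    Later passes re-score the merged corpus with the table's count floor and
    discount, so trigram phrases can form from a merged token plus a
    neighbor.  The underlying word multiset is never altered, only the
    grouping (splitting every joined token on ``_`` restores the input).
    """
    threshold = table.threshold if threshold is None else threshold
    passes = table.passes if passes is None else passes
    if passes < 1:
        raise ValueError("passes must be >= 1")
    current = corpus
    current_table = table
    for p in range(passes):
        if p > 0:
            current_table = score_bigrams(current, min_count=table.min_count,
                                          discount=table.discount)
        merged_posts = [
            Post(post.id, post.source, post.date, post.raw_text,
                 _merge_once(post.tokens, current_table, threshold))
            for post in current
        ]
        current = Corpus(merged_posts)
    return current


def unmerge(tokens: list[str]) -> list[str]:
    """Split phrase tokens back into their component words."""
    out: list[str] = []
    for t in tokens:
        out.extend(t.split(PHRASE_JOINER))
    return out
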
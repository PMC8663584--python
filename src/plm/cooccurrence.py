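"""Post-level lexicon mention counting and co-occurrence matrices.

The unit of co-occurrence is the post: two lexicons co-occur when at least
one active term of each appears in the same post, and the count is the
exact cardinality of the intersection of their post-id hit sets.  Matching
is exact token equality after the shared preprocessing (phrase terms match
their merged token); misspellings count only if they are explicit lexicon
members.  Percentages are reported to 2 decimals with round-half-even,
which reproduces printed ratios such as 413/3938 -> 10.49%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus
from .lexicon import Lexicon


@dataclass
class MentionEntry:
    """Hit set of one lexicon over the scanned posts."""

    lexicon: str
    post_ids: set[str]
    term_counts: dict[str, int]
    total_posts: int

    @property
    def mention_post_count(self) -> int:
        return len(self.post_ids)

    @property
    def fraction(self) -> float:
        return self.mention_post_count / self.total_posts

    @property
    def percent(self) -> float:
        """Percentage at 2 decimals, round-half-even."""
        return round(100.0 * self.fraction, 2)


@dataclass
class MentionTable:
    entries: dict[str, MentionEntry] = field(default_factory=dict)
    total_posts: int = 0

    def __getitem__(self, name: str) -> MentionEntry:
        if name not in self.entries:
            raise KeyError(f"unknown lexicon: {name!r}")
        return self.entries[name]

    def to_dict(self, include_hits: bool = True) -> dict:
        return {"total_posts": self.total_posts,
                "lexicons": {
                    name: {"mention_post_count": e.mention_post_count,
                           "percent": e.percent,
                           "term_counts": e.term_counts,
                           **({"post_ids": sorted(e.post_ids)}
                              if include_hits else {})}
                    for name, e in self.entries.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "MentionTable":
        total = d["total_posts"]
        entries = {}
        for name, rec in d["lexicons"].items():
            entries[name] = MentionEntry(
                lexicon=name, post_ids=set(rec.get("post_ids", [])),
                term_counts=dict(rec.get("term_counts", {})),
                total_posts=total)
        return cls(entries=entries, total_posts=total)

    def save(self, path: str | Path, include_hits: bool = True) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(include_hits), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "MentionTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def match_mentions(corpus: Corpus, lex: Lexicon) -> MentionEntry:
    """Scan the corpus for posts containing >= 1 active term of ``lex``.

    A post counts at most once toward the post count however many matches it
    contains; per-term raw occurrence counts are tallied separately.
    """
    active = set(lex.active_terms)
    if not active:
        raise ValueError(f"lexicon {lex.name!r} has no active terms")
    post_ids: set[str] = set()
    term_counts: dict[str, int] = {}
    for post in corpus:
        toks = post.tokens if post.tokens is not None else []
        hit = False
        for t in toks:
            if t in active:
                hit = True
                term_counts[t] = term_counts.get(t, 0) + 1
        if hit:
            post_ids.add(post.id)
    return MentionEntry(lexicon=lex.name, post_ids=post_ids,
                        term_counts=term_counts, total_posts=len(corpus))


def build_mention_table(corpus: Corpus, lexicons: list[Lexicon]) -> MentionTable:
    table = MentionTable(total_posts=len(corpus))
    for lex in lexicons:
        table.entries[lex.name] = match_mentions(corpus, lex)
    return table


@dataclass
class CooccurrenceMatrix:
    """Exact post-intersection counts, rows = symptom lexicons, columns =
    impact or severity lexicons, with mention-count marginals."""

    counts: pd.DataFrame  # int entries
    row_marginals: pd.Series
    col_marginals: pd.Series

    @property
    def rows(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cols(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out["__row_marginal__"] = self.row_marginals
        out.loc["__col_marginal__"] = list(self.col_marginals) + [np.nan]
        out.to_csv(path, sep="\t")


def cooccur(table: MentionTable, rows: list[str],
            cols: list[str]) -> CooccurrenceMatrix:
    """Pairwise post-level co-occurrence counts between named lexicons."""
    for name in list(rows) + list(cols):
        if name not in table.entries:
            raise KeyError(f"unknown lexicon: {name!r}")
    data = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            data[i, j] = len(table[r].post_ids & table[c].post_ids)
    counts = pd.DataFrame(data, index=list(rows), columns=list(cols))
    row_m = pd.Series({r: table[r].mention_post_count for r in rows})
    col_m = pd.Series({c: table[c].mention_post_count for c in cols})
    return CooccurrenceMatrix(counts=counts, row_marginals=row_m,
                              col_marginals=col_m)


def normalized_profiles(matrix: CooccurrenceMatrix,
                        mode: str = "by-row") -> pd.DataFrame:
    """Fractional profiles of a co-occurrence matrix.

    ``by-row`` divides each entry by the row lexicon's mention count (the
    share of row-mentioning posts that also mention the column lexicon);
    ``by-column`` symmetrically; ``by-total`` divides by the total number of
    scanned posts.  Zero-denominator rows/columns come back as NaN (absent),
    never 0/0.
    """
    c = matrix.counts.astype(float)
    if mode == "by-row":
        denom = matrix.row_marginals.astype(float).replace(0, np.nan)
        return c.div(denom, axis=0)
    if mode == "by-column":
        denom = matrix.col_marginals.astype(float).replace(0, np.nan)
        return c.div(denom, axis=1)
    if mode == "by-total":
        # the matrix does not store the scanned-post total, so by-total
        # normalizes by the sum of all entries
        s = float(matrix.counts.values.sum())
        return c / s if s > 0 else c * np.nan
    raise ValueError(f"unknown mode: {mode!r}")


def ordering_report(values: pd.DataFrame | CooccurrenceMatrix,
                    atol: float = 0.0) -> dict[str, list[dict]]:
    """Per-row ranking of column values, machine-readable, with tie flags.

    Each row maps to a list of {"column", "value", "rank", "tied_with_next"}
    records sorted descending by value (ties broken by column order).  Two
    values tie when they differ by at most ``atol``.
    """
    df = values.counts if isinstance(values, CooccurrenceMatrix) else values
    report: dict[str, list[dict]] = {}
    for row in df.index:
        vals = [(col, float(df.loc[row, col])) for col in df.columns]
        vals.sort(key=lambda cv: -cv[1])
        recs = []
        rank = 1
        for i, (col, v) in enumerate(vals):
            if i > 0 and abs(v - vals[i - 1][1]) > atol:
                rank = i + 1
            tied_next = (i + 1 < len(vals)
                         and abs(v - vals[i + 1][1]) <= atol)
            recs.append({"column": col, "value": v, "rank": rank,
                         "tied_with_next": tied_next})
        report[str(row)] = recs
    return report


def ranks_higher(report: dict[str, list[dict]], row: str, a: str, b: str) -> bool:
    """True if column ``a`` strictly outranks column ``b`` in ``row``."""
    recs = {r["column"]: r for r in report[row]}
    return recs[a]["rank"] < recs[b]["rank"]
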
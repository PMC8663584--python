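"""Post and corpus containers plus JSON-lines serialization.

A corpus is an ordered list of posts, each carrying an opaque id, a source
label, an optional calendar date, the raw text, and (after preprocessing) a
token list.  The post is the unit of all co-occurrence counting downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass
class Post:
    """One patient post.

    ``tokens`` is ``None`` until the text pipeline has run; afterwards it is
    a list of lowercase, non-empty token strings.
    """

    id: str
    source: str = "unknown"
    date: str | None = None
    raw_text: str = ""
    tokens: list[str] | None = None

    def to_record(self) -> dict:
        rec = {"id": self.id, "source": self.source, "date": self.date,
               "text": self.raw_text}
        if self.tokens is not None:
            rec["tokens"] = self.tokens
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Post":
        return cls(id=str(rec["id"]), source=rec.get("source", "unknown"),
                   date=rec.get("date"), raw_text=rec.get("text", ""),
                   tokens=rec.get("tokens"))


@dataclass
class Corpus:
    posts: list[Post] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    @property
    def n_tokens(self) -> int:
        """Total token count over all tokenized posts."""
        return sum(len(p.tokens) for p in self.posts if p.tokens is not None)

    def token_sequences(self) -> list[list[str]]:
        if any(p.tokens is None for p in self.posts):
            raise ValueError("corpus is not tokenized; run the text pipeline first")
        return [p.tokens for p in self.posts]

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.posts:
            if p.id in seen:
                raise ValueError(f"duplicate post id: {p.id!r}")
            seen.add(p.id)
            if p.tokens is not None:
                for t in p.tokens:
                    if not t or t != t.lower():
                        raise ValueError(
                            f"post {p.id!r}: token {t!r} is empty or not lowercase")


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for post in corpus:
            fh.write(json.dumps(post.to_record(), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> Corpus:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                posts.append(Post.from_record(json.loads(line)))
    corpus = Corpus(posts)
    corpus.validate()
    return corpus


def from_texts(texts: Iterable[str], source: str = "inline") -> Corpus:
    """Convenience constructor used throughout the tests."""
    return Corpus([Post(id=f"p{i}", source=source, raw_text=t)
                   for i, t in enumerate(texts)])
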
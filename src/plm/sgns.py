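"""Skip-gram negative-sampling (SGNS) word embeddings, from scratch.

The model learns one input vector ``w_in`` and one context vector ``w_out``
per vocabulary item by discriminating observed (center, context) pairs from
pairs whose context is drawn from a noise distribution.  For a center i,
positive context o and k noise draws, the per-pair loss minimized by SGD is

    L = -log sigma(w_out_o . w_in_i) - sum_neg log sigma(-w_out_neg . w_in_i)

with the noise distribution P_n(w) proportional to U(w)^0.75 (U = unigram
frequency) and frequent tokens subsampled with keep probability
min(1, sqrt(t / f)).  The window radius is sampled uniformly in [1, c] per
center token (dynamic window).  Training is single-threaded and fully
deterministic given the seed.

Similarity queries use the input vectors; context vectors are retained for
training diagnostics.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .corpus import Corpus

__all__ = [
    "Vocabulary", "TrainingConfig", "EmbeddingModel", "build_vocab",
    "noise_distribution", "subsample_keep_probability", "train",
    "cosine_similarity", "nearest_neighbors", "pair_loss", "pair_gradients",
    "save_model", "load_model",
]


@dataclass
class Vocabulary:
    """Dense token index with frequency counts (tokens below ``min_count``
    dropped).  Ordered by descending count, ties alphabetical."""

    tokens: list[str]
    counts: np.ndarray  # int64, aligned with tokens
    min_count: int
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequency(self, token: str) -> float:
        return self.counts[self.index[token]] / self.total


def build_vocab(corpus: Corpus, min_count: int = 5) -> Vocabulary:
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counter: Counter[str] = Counter()
    for toks in corpus.token_sequences():
        counter.update(toks)
    items = [(t, c) for t, c in counter.items() if c >= min_count]
    items.sort(key=lambda tc: (-tc[1], tc[0]))
    tokens = [t for t, _ in items]
    counts = np.array([c for _, c in items], dtype=np.int64)
    return Vocabulary(tokens=tokens, counts=counts, min_count=min_count)


def noise_distribution(vocab: Vocabulary, exponent: float = 0.75) -> np.ndarray:
    """Negative-sampling distribution P_n(w) ∝ U(w)^exponent; sums to 1."""
    if len(vocab) == 0:
        raise ValueError("noise_distribution: empty vocabulary")
    if not 0.0 < exponent <= 1.0:
        raise ValueError("noise exponent must be in (0, 1]")
    p = vocab.counts.astype(np.float64) ** exponent
    return p / p.sum()


def subsample_keep_probability(f: float, t: float) -> float:
    """Keep probability min(1, sqrt(t/f)) for a token of relative frequency f."""
    if f <= 0:
        raise ValueError("relative frequency must be > 0")
    if t <= 0:
        raise ValueError("subsample threshold must be > 0")
    return min(1.0, math.sqrt(t / f))


@dataclass
class TrainingConfig:
    dimension: int = 100
    window: int = 5
    negatives: int = 5
    subsample: float = 1e-4
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    noise_exponent: float = 0.75
    min_count: int = 5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.subsample <= 0:
            raise ValueError("subsample threshold must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 < self.noise_exponent <= 1.0:
            raise ValueError("noise_exponent must be in (0, 1]")


@dataclass
class EmbeddingModel:
    w_in: np.ndarray   # V x d, float32; used for similarity queries and PCA
    w_out: np.ndarray  # V x d, float32; training-side context vectors
    vocab: Vocabulary
    config: TrainingConfig
    epoch_mean_loss: list[float] = field(default_factory=list)
    # mean loss over a fixed reference pair sample (the first epoch's
    # pairs): entry 0 at the initial weights, entry e after epoch e
    eval_mean_loss: list[float] = field(default_factory=list)

    def vector(self, token: str) -> np.ndarray:
        if token not in self.vocab:
            raise KeyError(f"token not in vocabulary: {token!r}")
        return self.w_in[self.vocab.index[token]]

    def nearest_neighbors(self, query: str, k: int = 10):
        return nearest_neighbors(self, query, k)


# ---------------------------------------------------------------------------
# Pair objective (pure NumPy; the reference the kernels and the gradient
# check are held against)

def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))),
                    x - np.log1p(np.exp(-np.abs(x))))


def pair_loss(w_in_i: np.ndarray, w_out_o: np.ndarray,
              w_out_neg: np.ndarray) -> float:
    """SGNS loss for one (center, context) pair with a k x d negative block."""
    s_pos = float(np.dot(w_in_i, w_out_o))
    s_neg = w_out_neg @ w_in_i
    return float(-_log_sigmoid(s_pos) - _log_sigmoid(-s_neg).sum())


def pair_gradients(w_in_i: np.ndarray, w_out_o: np.ndarray,
                   w_out_neg: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of ``pair_loss`` w.r.t. each argument."""
    sig_pos = 1.0 / (1.0 + np.exp(-np.dot(w_in_i, w_out_o)))
    sig_neg = 1.0 / (1.0 + np.exp(-(w_out_neg @ w_in_i)))
    g_in = (sig_pos - 1.0) * w_out_o + sig_neg @ w_out_neg
    g_out_o = (sig_pos - 1.0) * w_in_i
    g_out_neg = sig_neg[:, None] * w_in_i[None, :]
    return g_in, g_out_o, g_out_neg


# ---------------------------------------------------------------------------
# Numba kernels: sequential SGD, deterministic given the pregenerated pair /
# negative / learning-rate arrays.

@njit(cache=True, fastmath=False)
def _stable_pieces(s):
    # returns (sigma(s), -log sigma(s), -log sigma(-s))
    if s >= 0.0:
        e = math.exp(-s)
        sig = 1.0 / (1.0 + e)
        return sig, math.log1p(e), s + math.log1p(e)
    e = math.exp(s)
    sig = e / (1.0 + e)
    return sig, -s + math.log1p(e), math.log1p(e)


@njit(cache=True, fastmath=False)
def _sgns_epoch(w_in, w_out, centers, contexts, negatives, alphas, update):
    n_pairs = centers.shape[0]
    k = negatives.shape[1]
    d = w_in.shape[1]
    total_loss = 0.0
    neu = np.zeros(d, dtype=np.float32)
    for p in range(n_pairs):
        ci = centers[p]
        lr = alphas[p]
        for j in range(d):
            neu[j] = 0.0
        # positive context, then the k noise rows
        for r in range(k + 1):
            row = contexts[p] if r == 0 else negatives[p, r - 1]
            s = 0.0
            for j in range(d):
                s += float(w_in[ci, j]) * float(w_out[row, j])
            sig, nls_pos, nls_neg = _stable_pieces(s)
            if r == 0:
                total_loss += nls_pos
                g = lr * (1.0 - sig)
            else:
                total_loss += nls_neg
                g = lr * (0.0 - sig)
            if update:
                for j in range(d):
                    neu[j] += np.float32(g) * w_out[row, j]
                    w_out[row, j] += np.float32(g) * w_in[ci, j]
        if update:
            for j in range(d):
                w_in[ci, j] += neu[j]
    return total_loss


@njit(cache=True, fastmath=False)
def _build_pairs(kept, offsets, radii, centers, contexts):
    n = 0
    for p in range(offsets.shape[0] - 1):
        start = offsets[p]
        end = offsets[p + 1]
        for i in range(start, end):
            b = radii[i]
            lo = i - b if i - b > start else start
            hi = i + b + 1 if i + b + 1 < end else end
            for j in range(lo, hi):
                if j != i:
                    centers[n] = kept[i]
                    contexts[n] = kept[j]
                    n += 1
    return n


def _draw_negatives(rng: np.random.Generator, cdf: np.ndarray, contexts:
                    np.ndarray, k: int) -> np.ndarray:
    negs = np.searchsorted(cdf, rng.random((contexts.shape[0], k))
                           ).astype(np.int32)
    # a noise draw equal to the positive context is resampled
    if cdf.shape[0] > 1:
        for _ in range(64):
            clash = negs == contexts[:, None]
            if not clash.any():
                break
            negs[clash] = np.searchsorted(
                cdf, rng.random(int(clash.sum()))).astype(np.int32)
    return negs


def train(corpus: Corpus, config: TrainingConfig | None = None) -> EmbeddingModel:
    """Train an SGNS embedding on a tokenized corpus.

    Windows never cross post boundaries.  Subsampling, window radii and
    negative draws are regenerated each epoch from the single seeded
    generator, so the whole run is reproducible bit-for-bit.
    ``epoch_mean_loss[0]`` is the mean pair loss of the first epoch's pairs
    evaluated at the initial weights (no updates); subsequent entries are
    the running mean loss of each training epoch.
    """
    config = config or TrainingConfig()
    config.validate()
    vocab = build_vocab(corpus, config.min_count)
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty after applying min_count")

    index = vocab.index
    seq_list = []
    for toks in corpus.token_sequences():
        ids = [index[t] for t in toks if t in index]
        if ids:
            seq_list.append(np.array(ids, dtype=np.int32))
    flat = np.concatenate(seq_list) if seq_list else np.empty(0, np.int32)
    post_of = np.repeat(np.arange(len(seq_list)),
                        [len(s) for s in seq_list])

    freqs = vocab.counts / vocab.total
    keep_prob = np.minimum(1.0, np.sqrt(config.subsample / freqs))
    cdf = np.cumsum(noise_distribution(vocab, config.noise_exponent))

    rng = np.random.default_rng(config.rng_seed)
    d = config.dimension
    w_in = ((rng.random((len(vocab), d)) - 0.5) / d).astype(np.float32)
    w_out = np.zeros((len(vocab), d), dtype=np.float32)

    losses: list[float] = []
    eval_losses: list[float] = []
    ref_pairs = None  # fixed (centers, contexts, negatives) for eval loss
    zero_alpha = None
    for epoch in range(config.epochs):
        keep = rng.random(flat.shape[0]) < keep_prob[flat]
        kept = flat[keep]
        kept_posts = post_of[keep]
        if kept.shape[0] == 0:
            losses.append(float("nan"))
            continue
        counts = np.bincount(kept_posts, minlength=len(seq_list))
        offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        radii = rng.integers(1, config.window + 1,
                             size=kept.shape[0]).astype(np.int64)
        cap = int(2 * radii.sum())
        centers = np.empty(cap, dtype=np.int32)
        contexts = np.empty(cap, dtype=np.int32)
        n_pairs = _build_pairs(kept, offsets, radii, centers, contexts)
        centers, contexts = centers[:n_pairs], contexts[:n_pairs]
        if n_pairs == 0:
            losses.append(float("nan"))
            continue
        negs = _draw_negatives(rng, cdf, contexts, config.negatives)
        prog = (epoch + np.arange(n_pairs) / n_pairs) / config.epochs
        alphas = config.alpha + (config.min_alpha - config.alpha) * prog
        if epoch == 0:
            ref_pairs = (centers, contexts, negs)
            zero_alpha = np.zeros(n_pairs)
            init_loss = _sgns_epoch(w_in, w_out, centers, contexts, negs,
                                    zero_alpha, False)
            losses.append(init_loss / n_pairs)
            eval_losses.append(init_loss / n_pairs)
        total = _sgns_epoch(w_in, w_out, centers, contexts, negs, alphas, True)
        losses.append(total / n_pairs)
        eval_losses.append(_sgns_epoch(w_in, w_out, *ref_pairs, zero_alpha,
                                       False) / ref_pairs[0].shape[0])
        if not math.isfinite(losses[-1]):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {losses[-1]}")

    if not np.isfinite(w_in).all() or not np.isfinite(w_out).all():
        raise FloatingPointError("non-finite entries in trained vectors")
    return EmbeddingModel(w_in=w_in, w_out=w_out, vocab=vocab, config=config,
                          epoch_mean_loss=losses, eval_mean_loss=eval_losses)


# ---------------------------------------------------------------------------
# Similarity queries

def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def nearest_neighbors(model: EmbeddingModel, query: str, k: int = 10
                      ) -> list[tuple[str, float]]:
    """Top-k vocabulary items by cosine to the query's input vector.

    The query itself is excluded; ties broken by vocabulary index ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if query not in model.vocab:
        raise KeyError(f"token not in vocabulary: {query!r}")
    qi = model.vocab.index[query]
    w = model.w_in.astype(np.float64)
    norms = np.linalg.norm(w, axis=1)
    norms[norms == 0.0] = 1.0
    sims = (w @ (w[qi] / norms[qi])) / norms
    order = np.argsort(-sims, kind="stable")  # stable => ties by index asc
    out = []
    for i in order:
        if i == qi:
            continue
        out.append((model.vocab.tokens[i], float(sims[i])))
        if len(out) == k:
            break
    return out


# ---------------------------------------------------------------------------
# Persistence: word2vec text format + JSON sidecar

def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Write input vectors in the word2vec text format ("V d" header, one
    token + d numbers per line) with a ``.json`` sidecar holding the config,
    counts and context vectors."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.vocab)} {model.config.dimension}\n")
        for i, tok in enumerate(model.vocab.tokens):
            nums = " ".join(f"{x:.9e}" for x in model.w_in[i])
            fh.write(f"{tok} {nums}\n")
    sidecar = {
        "config": asdict(model.config),
        "counts": {t: int(c) for t, c in
                   zip(model.vocab.tokens, model.vocab.counts)},
        "min_count": model.vocab.min_count,
        "epoch_mean_loss": model.epoch_mean_loss,
        "eval_mean_loss": model.eval_mean_loss,
        "w_out": [[f"{x:.9e}" for x in row] for row in model.w_out],
    }
    with open(path.with_suffix(path.suffix + ".json"), "w",
              encoding="utf-8") as fh:
        json.dump(sidecar, fh)


def load_model(path: str | Path) -> EmbeddingModel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        v_size, dim = int(header[0]), int(header[1])
        tokens, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            tokens.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float32))
    if len(tokens) != v_size:
        raise ValueError(f"vector file header claims {v_size} rows, "
                         f"found {len(tokens)}")
    w_in = np.vstack(rows) if rows else np.empty((0, dim), np.float32)
    with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    config = TrainingConfig(**sidecar["config"])
    counts = np.array([sidecar["counts"][t] for t in tokens], dtype=np.int64)
    vocab = Vocabulary(tokens=tokens, counts=counts,
                       min_count=sidecar["min_count"])
    w_out = np.array([[np.float32(x) for x in row]
                      for row in sidecar["w_out"]], dtype=np.float32)
    if w_out.size == 0:
        w_out = np.zeros_like(w_in)
    return EmbeddingModel(w_in=w_in, w_out=w_out, vocab=vocab, config=config,
                          epoch_mean_loss=list(sidecar["epoch_mean_loss"]),
                          eval_mean_loss=list(sidecar.get("eval_mean_loss", [])))
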
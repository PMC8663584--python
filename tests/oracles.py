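"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np

from plm.corpus import Corpus


def bigram_counts_bruteforce(corpus: Corpus) -> dict[tuple[str, str], int]:
    """Exhaustive index-pair scan for adjacent within-post bigram counts."""
    counts: dict[tuple[str, str], int] = {}
    for toks in corpus.token_sequences():
        for i in range(len(toks) - 1):
            key = (toks[i], toks[i + 1])
            counts[key] = counts.get(key, 0) + 1
    return counts


def unigram_counts_bruteforce(corpus: Corpus) -> dict[str, int]:
    counts: dict[str, int] = {}
    for toks in corpus.token_sequences():
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    return counts


def cooccur_bruteforce(corpus: Corpus, terms_a: set[str],
                       terms_b: set[str]) -> int:
    """Double loop over posts: count posts containing a term of both sets."""
    n = 0
    for post in corpus:
        has_a = False
        has_b = False
        for t in post.tokens:
            if t in terms_a:
                has_a = True
            if t in terms_b:
                has_b = True
        if has_a and has_b:
            n += 1
    return n


def nearest_bruteforce(model, query: str, k: int) -> list[tuple[str, float]]:
    """Per-token cosine loop, independent of the vectorized query path."""
    qv = model.w_in[model.vocab.index[query]].astype(np.float64)
    sims = []
    for i, tok in enumerate(model.vocab.tokens):
        if tok == query:
            continue
        v = model.w_in[i].astype(np.float64)
        c = float(qv @ v / (np.linalg.norm(qv) * np.linalg.norm(v)))
        sims.append((tok, c, i))
    sims.sort(key=lambda tc: (-tc[1], tc[2]))
    return [(t, c) for t, c, _ in sims[:k]]


def pca_eig_oracle(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA by explicit eigendecomposition of the covariance matrix.

    Returns (coordinates, eigenvalue-ratios over all components).
    """
    xc = x - x.mean(axis=0, keepdims=True)
    cov = xc.T @ xc / (x.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = xc @ vecs[:, :n_components]
    vals = np.clip(vals, 0, None)
    return coords, vals / vals.sum()


def ppmi_svd_embedding(corpus: Corpus, window: int = 5, dim: int = 50,
                       min_count: int = 2, cds: float = 0.75):
    """Count-based embedding: positive PMI of windowed co-occurrence, SVD.

    Context counts are smoothed with exponent ``cds`` before normalizing.
    An independent route to "similar contexts -> nearby vectors", used as a
    soft cross-check of the SGNS neighbor structure.
    """
    counts = unigram_counts_bruteforce(corpus)
    tokens = sorted(t for t, c in counts.items() if c >= min_count)
    index = {t: i for i, t in enumerate(tokens)}
    v = len(tokens)
    mat = np.zeros((v, v))
    for toks in corpus.token_sequences():
        ids = [index.get(t, -1) for t in toks]
        for i, ci in enumerate(ids):
            if ci < 0:
                continue
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i and ids[j] >= 0:
                    mat[ci, ids[j]] += 1.0
    joint = mat / mat.sum()
    row = mat.sum(axis=1, keepdims=True)
    row = row / row.sum()
    col = mat.sum(axis=0) ** cds
    col = col / col.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(joint / (row * col[None, :]))
    pmi[~np.isfinite(pmi)] = 0.0
    pmi = np.clip(pmi, 0.0, None)
    u, s, _ = np.linalg.svd(pmi, full_matrices=False)
    emb = u[:, :dim] * np.sqrt(s[:dim])
    return tokens, index, emb


def ppmi_neighbors(tokens, index, emb, query: str, k: int) -> list[str]:
    qv = emb[index[query]]
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    sims = emb @ qv / (norms * (np.linalg.norm(qv) or 1.0))
    order = np.argsort(-sims)
    out = [tokens[i] for i in order if tokens[i] != query]
    return out[:k]
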
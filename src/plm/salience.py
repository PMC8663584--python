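"""PCA salience map: 2D projection of lexicon-member vectors.

Lexicon members' input vectors are L2-normalized (so Euclidean geometry in
the projection approximates cosine geometry in the embedding — an explicit
convention, see docs), column-mean-centered, and projected onto the top
principal axes obtained by SVD.  Per-axis sign is fixed by making the
largest-magnitude loading positive, so repeated projection is bit-identical.
"Psychological salience" of a symptom cluster is operationalized as the
Euclidean distance of its 2D centroid from the affective-states centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .sgns import EmbeddingModel

_EPS = 1e-12


@dataclass
class SalienceMap:
    coords: pd.DataFrame            # columns: term, lexicon, x, y (or pc1..pcn)
    components: np.ndarray          # n_components x d projection basis
    explained_ratio: np.ndarray     # variance-explained of ALL components
    centroids: dict[str, np.ndarray]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (lexicon, term) OOV

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        self.coords.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "explained_ratio": [float(x) for x in
                                self.explained_ratio[:self.n_components]],
            "centroids": {k: [float(x) for x in v]
                          for k, v in self.centroids.items()},
            "skipped": [list(s) for s in self.skipped],
        }


def project(model: EmbeddingModel, lexicons: list[Lexicon],
            n_components: int = 2, normalize: bool = True) -> SalienceMap:
    """Project all active lexicon terms onto the top principal axes.

    One point per (lexicon, term) pair; out-of-vocabulary terms are reported
    in ``skipped`` rather than failing the projection.  ``normalize`` (the
    default) L2-normalizes vectors before centering so the 2D geometry
    approximates cosine geometry; with ``normalize=False`` the map is
    invariant under a constant shift of all embedding rows.  Deterministic:
    the per-axis sign convention makes the largest-|loading| coordinate
    positive.
    """
    rows, labels, skipped = [], [], []
    for lex in lexicons:
        for term in lex.active_terms:
            if term in model.vocab:
                v = model.w_in[model.vocab.index[term]].astype(np.float64)
                nrm = np.linalg.norm(v)
                if nrm > 0:
                    rows.append(v / nrm if normalize else v)
                    labels.append((lex.name, term))
                    continue
            skipped.append((lex.name, term))
    if len(rows) < max(3, n_components + 1):
        raise ValueError(
            f"need at least {max(3, n_components + 1)} in-vocabulary terms, "
            f"got {len(rows)}")

    x = np.vstack(rows)
    xc = x - x.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each axis is positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    total_var = float((s ** 2).sum())
    explained = (s ** 2) / total_var if total_var > 0 else s * 0.0
    comp = vt[:n_components]
    proj = xc @ comp.T

    coord_cols = {0: "x", 1: "y"}
    data = {"lexicon": [l for l, _ in labels], "term": [t for _, t in labels]}
    for i in range(n_components):
        data[coord_cols.get(i, f"pc{i + 1}")] = proj[:, i]
    coords = pd.DataFrame(data)

    centroids = {}
    for name in dict.fromkeys(l for l, _ in labels):
        mask = coords["lexicon"] == name
        centroids[name] = proj[np.asarray(mask)].mean(axis=0)
    return SalienceMap(coords=coords, components=comp,
                       explained_ratio=explained, centroids=centroids,
                       skipped=skipped)


def centroid_distances(smap: SalienceMap, reference: str
                       ) -> list[tuple[str, float, bool]]:
    """Euclidean distances of each lexicon centroid to the reference
    centroid, ascending; the third field flags a tie with the next entry."""
    if reference not in smap.centroids:
        raise KeyError(f"unknown reference lexicon: {reference!r}")
    ref = smap.centroids[reference]
    dists = sorted((name, float(np.linalg.norm(c - ref)))
                   for name, c in smap.centroids.items() if name != reference)
    dists.sort(key=lambda nd: nd[1])
    out = []
    for i, (name, d) in enumerate(dists):
        tied = i + 1 < len(dists) and abs(d - dists[i + 1][1]) <= _EPS
        out.append((name, d, tied))
    return out


def axis_alignment(smap: SalienceMap, lex_a: str, lex_b: str,
                   reference: str) -> float | None:
    """|cos angle| between the two centroid displacement vectors from the
    reference centroid; 1 = perfectly collinear, None if a centroid
    coincides with the reference (undefined)."""
    for name in (lex_a, lex_b, reference):
        if name not in smap.centroids:
            raise KeyError(f"unknown lexicon: {name!r}")
    ref = smap.centroids[reference]
    va = smap.centroids[lex_a] - ref
    vb = smap.centroids[lex_b] - ref
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < _EPS or nb < _EPS:
        return None
    return float(abs(np.dot(va, vb) / (na * nb)))


def save_summary(smap: SalienceMap, reference: str | None,
                 path: str | Path) -> None:
    summary = smap.summary()
    if reference is not None and reference in smap.centroids:
        summary["reference"] = reference
        summary["centroid_distances"] = [
            {"lexicon": n, "distance": d, "tied_with_next": t}
            for n, d, t in centroid_distances(smap, reference)]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
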
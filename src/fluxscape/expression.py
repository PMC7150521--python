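"""Expression-based metabolic-state clustering.

Validates the four-attractor picture against expression data: each
sample gets a glycolysis score and an OXPHOS score (means of per-gene
normalized expression over the two gene groups), and K-means with k=4
on the score plane assigns samples to metabolic states.  Cluster ids
are canonicalized by centroid geometry (1 = both-low normal-like,
2 = glycolysis-high, 3 = OXPHOS-high, 4 = intermediate) so labels are
comparable across runs and seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "compute_group_scores",
    "cluster_states",
    "read_expression_matrix",
    "read_gene_list",
    "STATE_NAMES",
]

STATE_NAMES = {1: "normal-like", 2: "glycolysis", 3: "OXPHOS", 4: "intermediate"}


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples tab-separated matrix with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def _normalize(values: pd.DataFrame, method: str) -> pd.DataFrame:
    if method == "zscore":
        mu = values.mean(axis=1)
        sd = values.std(axis=1, ddof=0)
        out = values.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        return out.fillna(0.0)  # zero-variance genes contribute 0
    if method == "minmax":
        lo = values.min(axis=1)
        rng = (values.max(axis=1) - lo).replace(0.0, np.nan)
        return values.sub(lo, axis=0).div(rng, axis=0).fillna(0.0)
    raise ValueError(f"unknown normalization {method!r}")


def compute_group_scores(matrix: pd.DataFrame, glycolysis_genes, oxphos_genes,
                         method: str = "zscore") -> pd.DataFrame:
    """Per-sample glycolysis and OXPHOS scores.

    Every gene is normalized across samples (z-score by default,
    min-max behind the flag), then scores are per-sample means within
    each group.  Genes missing from the matrix are skipped; a group
    with no matched genes is an error.
    """
    scores = {}
    for name, genes in (("glycolysis_score", glycolysis_genes),
                        ("oxphos_score", oxphos_genes)):
        present = [g for g in genes if g in matrix.index]
        if not present:
            raise ValueError(f"no genes of the {name.split('_')[0]} group found in matrix")
        normed = _normalize(matrix.loc[present].astype(float), method)
        scores[name] = normed.mean(axis=0)
    out = pd.DataFrame(scores)
    out.index.name = "sample"
    return out


def _canonical_labels(centers: np.ndarray) -> dict:
    """Map raw K-means cluster ids to canonical state ids 1..4."""
    k = len(centers)
    span = np.maximum(np.abs(centers).max(axis=0), 1e-12)
    Z = centers / span
    mapping = {}
    taken = set()
    refs = {1: Z.min(axis=0), 2: (Z[:, 0].max(), Z[:, 1].min()),
            3: (Z[:, 0].min(), Z[:, 1].max()), 4: Z.mean(axis=0)}
    cand = []
    for raw in range(k):
        for state, ref in refs.items():
            d = np.hypot(Z[raw, 0] - ref[0], Z[raw, 1] - ref[1])
            cand.append((d, raw, state))
    for _d, raw, state in sorted(cand):
        if raw in mapping or state in taken:
            continue
        mapping[raw] = state
        taken.add(state)
    # more than 4 clusters: remaining ids get sequential labels
    extra = 5
    for raw in range(k):
        if raw not in mapping:
            mapping[raw] = extra
            extra += 1
    return mapping


def cluster_states(scores: pd.DataFrame, k: int = 4, seed: int = 0,
                   n_init: int = 10) -> pd.DataFrame:
    """K-means on the 2D score plane with canonicalized cluster labels.

    Returns a copy of ``scores`` with a ``state`` column in {1..k}
    (1 normal-like, 2 glycolysis, 3 OXPHOS, 4 intermediate).
    """
    X = scores[["glycolysis_score", "oxphos_score"]].to_numpy(float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} samples, got {len(X)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    mapping = _canonical_labels(km.cluster_centers_)
    out = scores.copy()
    out["state"] = [mapping[r] for r in raw]
    return out
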
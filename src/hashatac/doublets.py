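"""Simulated-doublet scoring for binarized ATAC matrices.

Doublets are simulated as binarized sums (element-wise OR) of random pairs
of distinct cells. The IDF weighting is derived from observed cells before
simulation; observed and simulated profiles are embedded with that IDF, the
SVD basis is fit on observed cells and simulated doublets are projected onto
it. A cell's doublet score is the fraction of simulated doublets among its
k nearest neighbors in the (by default 49-dimensional, first-component-
dropped) embedding, and the top 10% of cells by score are pruned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .io import LabeledMatrix
from .qc import TfidfLsi

__all__ = ["simulate_doublets", "score_doublets", "prune_top_fraction",
           "DoubletDetector"]


def simulate_doublets(matrix: LabeledMatrix, n_sim: int, seed: int = 0
                      ) -> LabeledMatrix:
    """OR-combine ``n_sim`` random pairs of distinct cells."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    X = sp.csr_matrix(matrix.matrix)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 cells to simulate doublets")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_sim)
    j = rng.integers(0, n - 1, size=n_sim)
    j = np.where(j >= i, j + 1, j)  # distinct partner
    summed = X[i] + X[j]
    summed.data = np.ones_like(summed.data)
    names = [f"sim{t:05d}" for t in range(n_sim)]
    return LabeledMatrix(summed, names, matrix.col_names)


class DoubletDetector(BaseEstimator):
    """Modified-scrublet doublet scoring on a binary accessibility matrix.

    Parameters
    ----------
    n_sim : simulated doublet count (default: one per observed cell).
    n_components : SVD components before dropping the first (default 50,
        scoring space is therefore 49-dimensional).
    k : neighborhood size; default round(0.5 * sqrt(n_obs + n_sim)).
    frac : fraction of cells pruned (default 0.10).
    joint_basis : fit the SVD on observed + simulated jointly instead of
        projecting simulated profiles onto the observed basis.

    Fitted attributes: ``scores_`` (Series in [0,1]), ``pruned_`` (list).
    """

    def __init__(self, n_sim: int | None = None, n_components: int = 50,
                 drop_first: bool = True, k: int | None = None,
                 frac: float = 0.10, joint_basis: bool = False,
                 seed: int = 0):
        self.n_sim = n_sim
        self.n_components = n_components
        self.drop_first = drop_first
        self.k = k
        self.frac = frac
        self.joint_basis = joint_basis
        self.seed = seed

    def fit(self, matrix: LabeledMatrix, y=None):
        n = matrix.shape[0]
        n_sim = self.n_sim if self.n_sim is not None else n
        sim = simulate_doublets(matrix, n_sim, self.seed)

        lsi = TfidfLsi(n_components=self.n_components,
                       drop_first=self.drop_first)
        if self.joint_basis:
            joint = sp.vstack([sp.csr_matrix(matrix.matrix),
                               sp.csr_matrix(sim.matrix)])
            # IDF still from observed cells only
            col = np.asarray(matrix.matrix.sum(axis=0)).ravel()
            idf = np.where(col > 0, n / np.maximum(col, 1e-300), 1.0)
            lsi.idf = idf
            emb = lsi.fit(joint).embedding_
            obs_emb, sim_emb = emb[:n], emb[n:]
        else:
            obs_emb = lsi.fit(matrix.matrix,
                              row_names=matrix.row_names).embedding_
            sim_emb = lsi.transform(sim.matrix, row_names=sim.row_names)

        k = self.k if self.k is not None else max(
            int(round(0.5 * np.sqrt(n + n_sim))), 1)
        total = n + n_sim
        if k >= total:
            raise ValueError(f"k={k} must be < total points {total}")
        pts = np.vstack([obs_emb, sim_emb])
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, idx = nn.kneighbors(obs_emb)
        neigh = idx[:, 1:]  # drop self (an observed point is its own nearest)
        scores = (neigh >= n).mean(axis=1)
        self.scores_ = pd.Series(scores, index=matrix.row_names, name="score")
        self.k_ = k
        self.pruned_ = prune_top_fraction(self.scores_, self.frac)
        return self

    def fit_predict(self, matrix: LabeledMatrix):
        self.fit(matrix)
        return self.scores_.index.isin(self.pruned_)


def score_doublets(matrix: LabeledMatrix, n_sim: int | None = None,
                   dims: int = 49, k: int | None = None, seed: int = 0
                   ) -> pd.DataFrame:
    """Functional wrapper: score cells, return score/rank/pruned table."""
    det = DoubletDetector(n_sim=n_sim, n_components=dims + 1, k=k,
                          seed=seed).fit(matrix)
    df = pd.DataFrame({"score": det.scores_})
    df["rank"] = df["score"].rank(ascending=False, method="first").astype(int)
    df["pruned"] = df.index.isin(det.pruned_)
    return df


def prune_top_fraction(scores: pd.Series, frac: float = 0.10) -> list:
    """Barcodes of the top ``frac`` of cells by score.

    Exactly ceil(frac*n) removed; ties at the cutoff resolved by barcode
    order (lexicographic), making the rule deterministic.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    n_remove = int(np.ceil(frac * len(scores)))
    order = sorted(scores.index, key=lambda b: (-scores[b], b))
    return order[:n_remove]
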
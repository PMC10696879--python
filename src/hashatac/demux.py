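"""Hash-oligo demultiplexing of single-nucleus ATAC experiments.

Each nucleus carries a vector of hash UMI counts. Debris barcodes (below the
chromatin fragment threshold) define an ambient background profile; a
chi-squared goodness-of-fit test asks whether a nucleus's hash counts are
enriched over that background, and the ratio of the top to the second hash
(the enrichment score) separates singlets from multiplets. A nucleus is
called a singlet if it has >= `min_umis` total hash UMIs, a BH-adjusted
enrichment p-value below `p_thresh`, and an enrichment score >= `alpha`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._stats import bh_adjust
from .io import LabeledMatrix

log = logging.getLogger("hashatac")

__all__ = [
    "BackgroundProfile", "estimate_background", "chi2_enrichment_test",
    "enrichment_score", "assign_samples", "HashDemultiplexer",
    "evaluate_species_mix", "bh_adjust",
]


class BackgroundProfile:
    """Ambient per-hash proportions estimated from debris barcodes."""

    def __init__(self, proportions, hash_ids, n_debris: int):
        proportions = np.asarray(proportions, dtype=float)
        if np.any(proportions < 0):
            raise ValueError("background proportions must be non-negative")
        if abs(proportions.sum() - 1.0) > 1e-12:
            raise ValueError("background proportions must sum to 1")
        self.proportions = proportions
        self.hash_ids = list(hash_ids)
        self.n_debris = int(n_debris)


def estimate_background(matrix: LabeledMatrix, debris_barcodes) -> BackgroundProfile:
    """Mean hash-count vector over debris barcodes, normalized to proportions."""
    pos = {b: i for i, b in enumerate(matrix.row_names)}
    debris = [b for b in debris_barcodes if b in pos]
    if not debris:
        raise ValueError(
            "no debris barcodes found in the hash matrix; lower the "
            "chromatin fragment threshold so sub-threshold barcodes exist")
    idx = [pos[b] for b in debris]
    sub = matrix.matrix[idx]
    mean = np.asarray(sub.mean(axis=0)).ravel()
    total = mean.sum()
    if total <= 0:
        raise ValueError(
            "debris barcodes carry no hash UMIs; lower the chromatin "
            "fragment threshold to capture ambient hash signal")
    return BackgroundProfile(mean / total, matrix.col_names, len(debris))


def chi2_enrichment_test(counts, background: BackgroundProfile):
    """Goodness-of-fit of one nucleus's hash counts against the background.

    Hashes with zero background proportion are pooled into one extra
    category (their expected count would otherwise be zero). Returns
    (statistic, p) with df = (#categories) - 1 and an upper-tail p-value.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cell has zero hash UMIs; test undefined")
    props = background.proportions
    nz = props > 0
    if nz.sum() < 2:
        raise ValueError("background must have >= 2 nonzero proportions")
    obs = counts[nz]
    exp = props[nz] * total
    pooled = counts[~nz].sum()
    if pooled > 0:
        # expected mass for the pooled zero-background category is ~0; use a
        # tiny floor so the statistic is finite and the cell flags as enriched
        obs = np.append(obs, pooled)
        exp = exp * (1 - 1e-12)
        exp = np.append(exp, 1e-12 * total)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1
    return stat, float(stats.chi2.sf(stat, df))


def enrichment_score(counts) -> float:
    """Top-hash count over second-hash count; a lone observed hash scores
    its own count (avoiding infinities)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("cell has zero hash UMIs; enrichment undefined")
    order = np.sort(counts)[::-1]
    top, second = order[0], order[1] if len(order) > 1 else 0.0
    if second == 0:
        return float(top)
    return float(top / second)


class HashDemultiplexer(BaseEstimator):
    """Assign nuclei to samples from hash UMI counts.

    Parameters
    ----------
    min_umis : minimum total hash UMIs for a nucleus to be assignable.
    p_thresh : BH-adjusted enrichment p-value cutoff.
    alpha : minimum enrichment score for a singlet call (floored at 2).

    After :meth:`fit`, ``background_`` holds the ambient profile and
    ``assignments_`` the per-cell call table.
    """

    def __init__(self, min_umis: int = 10, p_thresh: float = 0.05,
                 alpha: float = 2.0):
        self.min_umis = min_umis
        self.p_thresh = p_thresh
        self.alpha = alpha

    def fit(self, matrix: LabeledMatrix, debris_barcodes,
            sample_map: dict | None = None):
        """Estimate background from debris and call every non-debris cell.

        sample_map optionally maps hash id -> sample label.
        """
        alpha = max(float(self.alpha), 2.0)
        self.background_ = estimate_background(matrix, debris_barcodes)
        debris = set(debris_barcodes)
        cells = [b for b in matrix.row_names if b not in debris]
        dense = matrix.to_frame().loc[cells]
        hash_ids = np.asarray(matrix.col_names)

        rows = []
        for cell, counts in zip(cells, dense.to_numpy()):
            total = int(counts.sum())
            if total == 0:
                rows.append((cell, None, None, total, np.nan, np.nan, np.nan))
                continue
            # deterministic tie-break: by hash id after count
            order = np.lexsort((hash_ids, -counts))
            top, second = order[0], (order[1] if len(order) > 1 else None)
            stat, p = chi2_enrichment_test(counts, self.background_)
            enr = enrichment_score(counts)
            rows.append((cell, hash_ids[top],
                         hash_ids[second] if second is not None else None,
                         total, stat, p, enr))
        df = pd.DataFrame(rows, columns=[
            "cell", "top_hash", "second_hash", "total_umis", "chi2", "p",
            "enrichment"]).set_index("cell", drop=False)
        df.index.name = None

        tested = df["p"].notna()
        padj = pd.Series(np.nan, index=df.index)
        if tested.any():
            padj[tested] = bh_adjust(df.loc[tested, "p"].to_numpy())
        df["padj"] = padj

        call = np.where(
            (df["total_umis"] >= self.min_umis) & (df["padj"] < self.p_thresh),
            np.where(df["enrichment"] >= alpha, "singlet", "multiplet"),
            "unassigned")
        df["call"] = call
        df["sample_label"] = [
            (sample_map or {}).get(h, h) if c == "singlet" else None
            for h, c in zip(df["top_hash"], df["call"])]
        df["alpha_used"] = alpha
        self.assignments_ = df
        return self

    def predict(self, matrix=None, debris_barcodes=None):
        if matrix is not None:
            self.fit(matrix, debris_barcodes)
        return self.assignments_["call"]


def assign_samples(matrix: LabeledMatrix, debris_barcodes, min_umis: int = 10,
                   p_thresh: float = 0.05, alpha: float = 2.0,
                   sample_map: dict | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`HashDemultiplexer`."""
    return HashDemultiplexer(min_umis, p_thresh, alpha).fit(
        matrix, debris_barcodes, sample_map).assignments_


def evaluate_species_mix(species_counts: pd.DataFrame,
                         assignments: pd.DataFrame,
                         purity: float = 0.90) -> dict:
    """Cross-tabulate chromatin species collisions against hash calls.

    A chromatin collision is a barcode with < ``purity`` of its fragments on
    a single species (strict inequality). Zero-fragment cells are excluded
    with a logged count. Returns a report dict with per-cell table, the
    collision/multiplet crosstab, and summary rates.
    """
    if species_counts.shape[1] != 2:
        raise ValueError("expected exactly two species columns")
    totals = species_counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        log.info("evaluate_species_mix: excluded %d zero-fragment cells",
                 int(zero.sum()))
    sc = species_counts.loc[~zero]
    totals = totals[~zero]
    frac = sc.div(totals, axis=0)
    max_frac = frac.max(axis=1)
    collision = max_frac < purity
    species = frac.idxmax(axis=1).where(~collision, "mixed")

    table = pd.DataFrame({
        "max_species_fraction": max_frac,
        "chromatin_collision": collision,
        "species": species,
    })
    joined = table.join(assignments[["call"]], how="inner")
    joined["hash_multiplet"] = joined["call"] != "singlet"
    crosstab = pd.crosstab(joined["chromatin_collision"],
                           joined["hash_multiplet"])
    n_coll = int(joined["chromatin_collision"].sum())
    flagged = int((joined["chromatin_collision"]
                   & joined["hash_multiplet"]).sum())
    return {
        "table": table,
        "crosstab": crosstab,
        "collision_rate": float(joined["chromatin_collision"].mean()),
        "hash_capture_rate": flagged / n_coll if n_coll else np.nan,
        "n_collisions": n_coll,
        "n_cells": int(len(joined)),
    }
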
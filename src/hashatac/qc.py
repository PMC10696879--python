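"""Per-cell QC metrics, filtering, binarized matrices, and TF-IDF/LSI.

QC metrics: total fragments; fraction of reads in peaks (FRIP: fragments
overlapping called peaks over all fragments); and a TSS enrichment score
defined as the per-base insertion rate in TSS +/- 50 bp over the per-base
rate in 100-bp flanks centered at +/- 1950 bp, aggregated across TSSs.
Cells pass QC with >= 500 fragments and TSS enrichment >= 3 (inclusive);
sub-fragment-threshold barcodes form the debris set used for the hash
background. Binary accessibility matrices keep features accessible in at
least a configurable fraction of cells (0.5% for genome-wide tiles).
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FragmentRecord, LabeledMatrix

log = logging.getLogger("hashatac")

__all__ = [
    "compute_cell_qc", "filter_cells", "FilterResult", "build_binary_matrix",
    "TfidfLsi", "tfidf_lsi",
]


def _fragments_frame(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        return fragments
    rows = [(f.chrom, f.start, f.end, f.barcode, f.count) for f in fragments]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode",
                                       "count"])


def _merge_intervals(starts, ends):
    order = np.argsort(starts)
    starts, ends = np.asarray(starts)[order], np.asarray(ends)[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def _in_intervals(pos, starts, ends):
    """Membership of positions in merged, sorted half-open intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    return (pos >= starts[idx]) & (pos < ends[idx])


def compute_cell_qc(fragments, tss: pd.DataFrame, peaks: pd.DataFrame,
                    core_halfwidth: int = 50, flank_center: int = 1950,
                    flank_width: int = 100) -> pd.DataFrame:
    """Per-cell fragments, TSS enrichment, and FRIP.

    ``tss`` and ``peaks`` are BED-style frames (chrom/start/end). Cells with
    zero flank insertions but core signal get infinite enrichment; cells
    with no insertions near any TSS get NaN.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS set: TSS enrichment undefined")
    frags = _fragments_frame(fragments)

    cells = pd.Index(sorted(frags["barcode"].unique()))
    cpos = {c: i for i, c in enumerate(cells)}
    n = len(cells)
    total = np.zeros(n)
    in_peak = np.zeros(n)
    core = np.zeros(n)
    flank = np.zeros(n)

    for chrom, sub in frags.groupby("chrom", sort=False):
        ci = np.array([cpos[b] for b in sub["barcode"]])
        w = sub["count"].to_numpy(dtype=float)
        np.add.at(total, ci, w)

        pk = peaks[peaks["chrom"] == chrom]
        if len(pk):
            ps, pe = _merge_intervals(pk["start"].to_numpy(),
                                      pk["end"].to_numpy())
            # fragment overlaps a peak iff the first peak ending after its
            # start begins before its end (peaks merged + sorted)
            j = np.searchsorted(pe, sub["start"].to_numpy(), side="right")
            j = np.clip(j, 0, len(ps) - 1)
            hit = (ps[j] < sub["end"].to_numpy()) & \
                  (pe[j] > sub["start"].to_numpy())
            np.add.at(in_peak, ci, w * hit)

        ts = tss[tss["chrom"] == chrom]
        if len(ts):
            centers = ts["start"].to_numpy()
            cs, ce = _merge_intervals(centers - core_halfwidth,
                                      centers + core_halfwidth + 1)
            fs = np.concatenate([centers - flank_center - flank_width // 2,
                                 centers + flank_center - flank_width // 2])
            fe = fs + flank_width
            fs, fe = _merge_intervals(fs, fe)
            # Tn5 insertion sites: both fragment ends
            for pos in (sub["start"].to_numpy(), sub["end"].to_numpy() - 1):
                np.add.at(core, ci, w * _in_intervals(pos, cs, ce))
                np.add.at(flank, ci, w * _in_intervals(pos, fs, fe))

    core_width = 2 * core_halfwidth + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        core_rate = core / core_width
        flank_rate = flank / (2 * flank_width)
        tss_enr = np.where(flank_rate > 0, core_rate / flank_rate,
                           np.where(core_rate > 0, np.inf, np.nan))
        frip = np.where(total > 0, in_peak / total, np.nan)
    return pd.DataFrame({
        "cell": cells, "fragments": total.astype(int),
        "tss_enrichment": tss_enr, "frip": frip,
    }).set_index("cell", drop=False).rename_axis(None)


class FilterResult(NamedTuple):
    retained: list
    debris: list


def filter_cells(qc: pd.DataFrame, min_frags: int = 500,
                 min_tss: float = 3.0) -> FilterResult:
    """Inclusive QC filter; sub-fragment-threshold barcodes become debris."""
    keep = (qc["fragments"] >= min_frags) & (qc["tss_enrichment"] >= min_tss)
    debris = qc.index[qc["fragments"] < min_frags].tolist()
    log.info("filter_cells: retained %d / %d cells (%d debris)",
             int(keep.sum()), len(qc), len(debris))
    return FilterResult(qc.index[keep].tolist(), debris)


def build_binary_matrix(fragments, features: pd.DataFrame,
                        min_cell_frac: float = 0.005) -> LabeledMatrix:
    """Binary cell x feature matrix: 1 iff >= 1 fragment overlaps the feature.

    Features accessible in fewer than ``min_cell_frac`` of cells are dropped;
    raises if nothing survives. Features must be non-overlapping per set.
    """
    frags = _fragments_frame(fragments)
    cells = pd.Index(sorted(frags["barcode"].unique()))
    cpos = {c: i for i, c in enumerate(cells)}
    feat_names = (features["name"].tolist() if "name" in features.columns
                  else [f"{c}:{s}-{e}" for c, s, e in
                        zip(features["chrom"], features["start"],
                            features["end"])])
    mat = sp.lil_matrix((len(cells), len(features)), dtype=np.int8)
    fpos_global = {}
    for chrom, pk in features.groupby("chrom", sort=False):
        order = np.argsort(pk["start"].to_numpy())
        ps = pk["start"].to_numpy()[order]
        pe = pk["end"].to_numpy()[order]
        gidx = pk.index.to_numpy()[order]
        fpos_global[chrom] = (ps, pe, gidx)
    feat_row = {idx: i for i, idx in enumerate(features.index)}
    for chrom, sub in frags.groupby("chrom", sort=False):
        if chrom not in fpos_global:
            continue
        ps, pe, gidx = fpos_global[chrom]
        j = np.searchsorted(pe, sub["start"].to_numpy(), side="right")
        j = np.clip(j, 0, len(ps) - 1)
        hit = (ps[j] < sub["end"].to_numpy()) & (pe[j] > sub["start"].to_numpy())
        ci = np.array([cpos[b] for b in sub["barcode"]])
        for c, jj, h in zip(ci, j, hit):
            if h:
                mat[c, feat_row[gidx[jj]]] = 1
    mat = sp.csr_matrix(mat)
    frac = np.asarray(mat.mean(axis=0)).ravel()
    keep = frac >= min_cell_frac
    if not keep.any():
        raise ValueError("no features pass the accessibility fraction filter")
    log.info("build_binary_matrix: %d/%d features retained",
             int(keep.sum()), len(keep))
    return LabeledMatrix(mat[:, keep], list(cells),
                         [f for f, k in zip(feat_names, keep) if k])


class TfidfLsi(BaseEstimator, TransformerMixin):
    """log(TF)*log(IDF) weighting followed by truncated SVD (LSI).

    TF_ij = x_ij / rowsum_i, transformed entry = ln(1 + scale*TF_ij) *
    ln(N / colsum_j). The IDF is learned on the fitted matrix (or supplied
    precomputed, e.g. derived before doublet simulation) and reused by
    :meth:`transform`, which projects new profiles onto the fitted SVD basis.
    Component signs are fixed by making each component's largest-magnitude
    feature loading positive. ``drop_first=True`` removes the depth-tracking
    first component from the returned embedding.
    """

    def __init__(self, n_components: int = 50, drop_first: bool = False,
                 scale: float = 1e4, idf: np.ndarray | None = None):
        self.n_components = n_components
        self.drop_first = drop_first
        self.scale = scale
        self.idf = idf

    def _weight(self, X, row_names=None):
        X = sp.csr_matrix(X, dtype=float)
        rows = np.asarray(X.sum(axis=1)).ravel()
        if np.any(rows == 0):
            bad = int(np.where(rows == 0)[0][0])
            name = row_names[bad] if row_names is not None else bad
            raise ValueError(f"cell {name!r} has an all-zero profile")
        tf = sp.diags(1.0 / rows) @ X
        tf.data = np.log1p(self.scale * tf.data)
        return tf.multiply(self.log_idf_[None, :]).tocsr()

    def fit(self, X, y=None, row_names=None):
        X = sp.csr_matrix(X, dtype=float)
        n, m = X.shape
        if self.idf is not None:
            idf = np.asarray(self.idf, dtype=float)
        else:
            col = np.asarray(X.sum(axis=0)).ravel()
            with np.errstate(divide="ignore"):
                idf = np.where(col > 0, n / np.maximum(col, 1e-300), 1.0)
        self.idf_ = idf
        self.log_idf_ = np.where(idf > 0, np.log(idf), 0.0)
        W = self._weight(X, row_names)
        k = min(self.n_components, min(n, m) - 1)
        from scipy.sparse.linalg import svds

        u, s, vt = svds(W, k=k, v0=np.ones(min(W.shape)))
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
        # deterministic sign: largest-|loading| positive per component
        for i in range(len(s)):
            j = np.argmax(np.abs(vt[i]))
            if vt[i, j] < 0:
                vt[i] *= -1
                u[:, i] *= -1
        self.components_ = vt
        self.singular_values_ = s
        self.embedding_ = u * s
        if self.drop_first:
            self.embedding_ = self.embedding_[:, 1:]
        return self

    def transform(self, X, row_names=None):
        W = self._weight(X, row_names)
        emb = W @ self.components_.T
        return np.asarray(emb)[:, 1:] if self.drop_first else np.asarray(emb)

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, **kw).embedding_


def tfidf_lsi(matrix: LabeledMatrix, dims: int = 50, drop_first: bool = False,
              idf: np.ndarray | None = None) -> TfidfLsi:
    """Fit LSI on a labeled binary matrix; returns the fitted estimator."""
    est = TfidfLsi(n_components=dims, drop_first=drop_first, idf=idf)
    est.fit(matrix.matrix, row_names=matrix.row_names)
    return est
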
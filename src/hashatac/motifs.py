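"""Motif trend enrichment and motif-based expression prediction.

Trend enrichment: one univariate logistic regression per motif predicting
whether a peak belongs to a given accessibility trend class from motif
presence; two-tailed Wald z p-values, BH-adjusted within each (trend,
condition) family; enriched means padj < 0.05 with a positive coefficient.

Expression models: for each gene with an accessible promoter (an ATAC peak
within 500 bp of its TSS), promoter features are binary motif indicators
over promoter peaks and distal features carry, per motif, the highest
co-accessibility score (>= 0.1 to count as connected) from a promoter peak
to a connected motif-bearing distal peak. Elastic-net regressions predict
the per-gene RNA dose coefficient from promoter-only or promoter+distal
features; the fold increase in variance explained quantifies the value of
distal sequence information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.preprocessing import StandardScaler

from ._stats import bh_adjust, fit_logistic_wald
from .io import LabeledMatrix

log = logging.getLogger("hashatac")

__all__ = [
    "motif_trend_regression", "MotifTrendEnrichment", "build_gene_features",
    "fit_expression_models", "ExpressionModel", "ExpressionModelResult",
]


def motif_trend_regression(in_class, motifs: LabeledMatrix,
                           trend: str = "", alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Per-motif logistic regression of trend membership on motif presence.

    ``in_class`` is a boolean vector over peaks (aligned with motif rows).
    Motifs present in all or no peaks are skipped as inestimable.
    """
    y = np.asarray(in_class, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need peaks both in and out of the trend class")
    M = np.asarray(motifs.matrix.todense(), dtype=float)
    rows = []
    for j, motif in enumerate(motifs.col_names):
        m = M[:, j]
        if m.sum() == 0 or m.sum() == len(m):
            rows.append(dict(motif=motif, trend=trend, beta=np.nan, z=np.nan,
                             p=np.nan, skipped=True))
            continue
        X = np.column_stack([np.ones(len(m)), m])
        res = fit_logistic_wald(y, X, coef_index=1)
        rows.append(dict(motif=motif, trend=trend, beta=res["beta"],
                         z=res["z"], p=res["p"],
                         skipped=res["separated"] or not res["converged"]))
    out = pd.DataFrame(rows)
    ok = out["p"].notna() & ~out["skipped"]
    out["padj"] = np.nan
    out.loc[ok, "padj"] = bh_adjust(out.loc[ok, "p"])
    out["enriched"] = (out["padj"] < alpha) & (out["beta"] > 0)
    return out


class MotifTrendEnrichment(BaseEstimator):
    """Estimator wrapper: fit per-trend motif enrichments.

    ``fit(trend_classes, motifs)`` runs one regression family per trend
    class (excluding 'static' peaks is the caller's choice); fitted
    attribute ``results_`` concatenates the per-trend tables.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, trend_classes: pd.Series, motifs: LabeledMatrix,
            trends=None):
        cls = trend_classes.reindex(motifs.row_names)
        trends = trends or [t for t in ["opening", "closing", "dynamic"]
                            if (cls == t).any()]
        tables = []
        for t in trends:
            tables.append(motif_trend_regression((cls == t).to_numpy(),
                                                 motifs, trend=t,
                                                 alpha=self.alpha))
        self.results_ = pd.concat(tables, ignore_index=True)
        return self


def build_gene_features(peaks: pd.DataFrame, tss: pd.DataFrame,
                        motifs: LabeledMatrix, links: pd.DataFrame,
                        threshold: float = 0.1, window: int = 500
                        ) -> pd.DataFrame:
    """Promoter and distal motif features per gene.

    A peak is a promoter peak for a gene if its interval lies within
    ``window`` bp of the TSS base (inclusive). Genes without a promoter
    peak are dropped (logged). Promoter feature per motif: 1 if any
    promoter peak carries it. Distal feature per motif: max link score
    >= ``threshold`` from a promoter peak to a motif-bearing linked peak,
    else 0. Links are treated as undirected.
    """
    motif_names = list(motifs.col_names)
    M = np.asarray(motifs.matrix.todense()).astype(bool)
    peak_idx = {p: i for i, p in enumerate(motifs.row_names)}
    name_col = "name" if "name" in peaks.columns else None
    if name_col is None:
        raise ValueError("peaks need a name column matching the motif matrix")

    # symmetrize links
    sym = pd.concat([
        links.rename(columns={"peak_a": "a", "peak_b": "b"}),
        links.rename(columns={"peak_a": "b", "peak_b": "a"}),
    ], ignore_index=True)[["a", "b", "score"]]
    sym = sym[sym["score"] >= threshold]
    by_peak = dict(tuple(sym.groupby("a", sort=True)))

    rows, dropped = [], 0
    for _, gene in tss.iterrows():
        gname = gene["name"]
        near = peaks[
            (peaks["chrom"] == gene["chrom"])
            & (peaks["start"] <= gene["start"] + window)
            & (peaks["end"] > gene["start"] - window)]
        prom_peaks = [p for p in near[name_col] if p in peak_idx]
        if not prom_peaks:
            dropped += 1
            continue
        prom = np.zeros(len(motif_names))
        for p in prom_peaks:
            prom = np.maximum(prom, M[peak_idx[p]].astype(float))
        distal = np.zeros(len(motif_names))
        for p in prom_peaks:
            if p not in by_peak:
                continue
            for _, link in by_peak[p].iterrows():
                other = link["b"]
                if other in peak_idx and other not in prom_peaks:
                    has = M[peak_idx[other]]
                    distal[has] = np.maximum(distal[has], link["score"])
        rows.append(pd.Series(
            np.concatenate([prom, distal]),
            index=[f"promoter_{m}" for m in motif_names]
            + [f"distal_{m}" for m in motif_names], name=gname))
    if dropped:
        log.info("build_gene_features: dropped %d genes without an "
                 "accessible promoter peak", dropped)
    if not rows:
        raise ValueError("no genes with accessible promoter peaks")
    return pd.DataFrame(rows)


@dataclass
class ExpressionModelResult:
    drug: str
    variant: str                      # promoter_only / promoter_and_distal
    coefficients: pd.Series
    r2: float
    alpha: float
    l1_ratio: float


class ExpressionModel(BaseEstimator):
    """Elastic-net prediction of per-gene RNA dose coefficients.

    ``fit(features, target)`` fits two penalized linear models (promoter
    features only; promoter + distal) with standardized features; penalty
    strength chosen by 5-fold cross-validation at a fixed mixing parameter.
    Variance explained is the training R-squared at the selected penalty;
    ``fold_increase_`` is the ratio full / promoter-only.
    """

    def __init__(self, l1_ratio: float = 0.5, cv: int = 5, seed: int = 0,
                 drug: str = ""):
        self.l1_ratio = l1_ratio
        self.cv = cv
        self.seed = seed
        self.drug = drug

    def _fit_variant(self, X: pd.DataFrame, y: np.ndarray, variant: str):
        scaler = StandardScaler()
        keep = X.columns[X.std(axis=0) > 0]
        Xs = scaler.fit_transform(X[keep])
        cv = ElasticNetCV(l1_ratio=self.l1_ratio, cv=self.cv,
                          random_state=self.seed, alphas=50,
                          max_iter=5000).fit(Xs, y)
        model = ElasticNet(alpha=cv.alpha_, l1_ratio=self.l1_ratio,
                           max_iter=5000).fit(Xs, y)
        coefs = pd.Series(0.0, index=X.columns)
        coefs[keep] = model.coef_
        r2 = float(model.score(Xs, y))
        return ExpressionModelResult(self.drug, variant, coefs, r2,
                                     float(cv.alpha_), self.l1_ratio)

    def fit(self, features: pd.DataFrame, target: pd.Series):
        common = features.index.intersection(target.index)
        if len(common) < 20:
            raise ValueError("need >= 20 genes with features and targets")
        y = target.loc[common].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("target coefficients have zero variance")
        X = features.loc[common]
        prom_cols = [c for c in X.columns if c.startswith("promoter_")]
        self.promoter_result_ = self._fit_variant(X[prom_cols], y,
                                                  "promoter_only")
        self.full_result_ = self._fit_variant(X, y, "promoter_and_distal")
        self.fold_increase_ = (
            self.full_result_.r2 / self.promoter_result_.r2
            if self.promoter_result_.r2 > 0 else np.inf)
        return self


def fit_expression_models(features: pd.DataFrame, target: pd.Series,
                          l1_ratio: float = 0.5, seed: int = 0,
                          drug: str = "") -> ExpressionModel:
    """Functional wrapper over :class:`ExpressionModel`."""
    return ExpressionModel(l1_ratio=l1_ratio, seed=seed, drug=drug).fit(
        features, target)
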
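"""Dose-response differential accessibility and related dose models.

Per-peak DA: for each drug D the cell set C is all D-treated cells plus all
vehicle cells; peaks accessible in >= 1% of C enter a logistic model
logit(Y) = b0 + bd*d + bf*f + bt*t where d is log-transformed dose, f is
ln(total fragments) and t the TSS enrichment score. The dose term is tested
by Wald z; raw p-values are pooled across all drugs and peaks before a
single Benjamini-Hochberg adjustment. Gene-level dose effects use a
quasipoisson log-link model ln(Y) = b0 + bd*d with library size factors as
offsets. Cell-recovery viability curves are fit with the four-parameter
log-logistic f(x) = c + (d - c) / (1 + exp(b (ln x - ln e))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._stats import SEPARATION_CAP, bh_adjust, fit_logistic_wald, fit_quasipoisson
from .io import LabeledMatrix

__all__ = [
    "add_log_dose", "subset_cells_for_drug", "run_peak_da", "DoseResponseDA",
    "fit_gene_dose_model", "compare_atac_rna_coeffs", "ViabilityFit",
    "fit_viability_4pl",
]


def add_log_dose(design: pd.DataFrame, base: float = 10.0) -> pd.DataFrame:
    """Add d = log(dose + delta), delta = (smallest nonzero dose)/10.

    The offset lets vehicle (dose 0) enter the model as a finite low value;
    delta is recorded in the ``log_dose_delta`` attribute column.
    """
    design = design.copy()
    nz = design.loc[design["dose"] > 0, "dose"]
    if nz.empty:
        raise ValueError("design has no nonzero doses")
    delta = nz.min() / 10.0
    design["d"] = np.log(design["dose"] + delta) / np.log(base)
    design["log_dose_delta"] = delta
    return design


def subset_cells_for_drug(design: pd.DataFrame, drug: str) -> pd.Index:
    """All cells treated with any dose of ``drug`` plus all vehicle cells."""
    treated = design.index[(design["drug"] == drug) & (design["dose"] > 0)]
    if len(treated) == 0:
        raise ValueError(f"no treated cells found for drug {drug!r}")
    vehicle = design.index[design["dose"] == 0]
    return treated.union(vehicle, sort=False)


class DoseResponseDA(BaseEstimator):
    """Per-peak logistic dose-response DA testing.

    Fit on a binary cell x peak matrix and a per-cell design (columns: drug,
    dose, d, f, t). ``results_`` holds one row per (drug, peak) with the
    dose coefficient, Wald test, pooled-BH adjusted p, direction, and flags.
    """

    def __init__(self, min_frac: float = 0.01, alpha: float = 0.05,
                 maxiter: int = 100):
        self.min_frac = min_frac
        self.alpha = alpha
        self.maxiter = maxiter

    def fit(self, matrix: LabeledMatrix, design: pd.DataFrame,
            drugs=None):
        design = design.loc[[c for c in matrix.row_names if c in design.index]]
        if "d" not in design.columns:
            design = add_log_dose(design)
        if drugs is None:
            drugs = sorted(set(design.loc[design["dose"] > 0, "drug"]))
        X = sp.csr_matrix(matrix.matrix)
        rowpos = {c: i for i, c in enumerate(matrix.row_names)}

        rows = []
        for drug in drugs:
            C = subset_cells_for_drug(design, drug)
            ridx = [rowpos[c] for c in C]
            sub = X[ridx].toarray()
            dsub = design.loc[C]
            if dsub["d"].nunique() < 2:
                raise ValueError(f"drug {drug!r}: need >= 2 distinct doses")
            frac = sub.mean(axis=0)
            Xd = np.column_stack([
                np.ones(len(C)), dsub["d"], dsub["f"], dsub["t"]])
            for j, peak in enumerate(matrix.col_names):
                if frac[j] < self.min_frac:
                    continue
                res = fit_logistic_wald(sub[:, j], Xd, coef_index=1,
                                        maxiter=self.maxiter)
                rows.append(dict(
                    peak=peak, drug=drug, beta_d=res["beta"], se=res["se"],
                    z=res["z"], p=res["p"], n_cells=len(C),
                    accessible_fraction=float(frac[j]),
                    flagged=(res["separated"] or not res["converged"]),
                ))
        results = pd.DataFrame(rows)
        if len(results):
            ok = results["p"].notna()
            results["padj"] = np.nan
            results.loc[ok, "padj"] = bh_adjust(results.loc[ok, "p"])
            results["direction"] = np.where(results["beta_d"] > 0, "opening",
                                            "closing")
            results["significant"] = ((results["padj"] < self.alpha)
                                      & ~results["flagged"])
        self.results_ = results
        return self


def run_peak_da(matrix: LabeledMatrix, design: pd.DataFrame,
                drug=None, min_frac: float = 0.01,
                alpha: float = 0.05) -> pd.DataFrame:
    """Functional wrapper over :class:`DoseResponseDA` (drug=None => all)."""
    drugs = None if drug in (None, "all") else [drug]
    return DoseResponseDA(min_frac=min_frac, alpha=alpha).fit(
        matrix, design, drugs=drugs).results_


def fit_gene_dose_model(matrix: LabeledMatrix, design: pd.DataFrame,
                        drug: str, size_factors: pd.Series) -> pd.DataFrame:
    """Quasipoisson ln(Y) = b0 + bd*d per gene, size factors as offsets."""
    if (np.asarray(size_factors) <= 0).any():
        raise ValueError("size factors must be positive")
    design = design.loc[[c for c in matrix.row_names if c in design.index]]
    if "d" not in design.columns:
        design = add_log_dose(design)
    C = subset_cells_for_drug(design, drug)
    rowpos = {c: i for i, c in enumerate(matrix.row_names)}
    Y = sp.csr_matrix(matrix.matrix)[[rowpos[c] for c in C]].toarray()
    dsub = design.loc[C]
    Xd = np.column_stack([np.ones(len(C)), dsub["d"]])
    offset = np.log(size_factors.loc[C].to_numpy())

    rows = []
    for j, gene in enumerate(matrix.col_names):
        y = Y[:, j]
        if y.sum() == 0:
            rows.append(dict(gene=gene, beta_d=np.nan, se=np.nan, p=np.nan,
                             flagged=True))
            continue
        res = fit_quasipoisson(y, Xd, coef_index=1, offset=offset)
        rows.append(dict(gene=gene, beta_d=res["beta"], se=res["se"],
                         p=res["p"], flagged=False))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["padj"] = np.nan
    out.loc[ok, "padj"] = bh_adjust(out.loc[ok, "p"])
    return out


def compare_atac_rna_coeffs(atac: pd.DataFrame, rna: pd.DataFrame,
                            rna_alpha: float = 0.05) -> dict:
    """Join per-gene dose coefficients; keep genes with significant RNA dose
    terms; report Pearson correlation and sign concordance."""
    sig = rna[(rna["padj"] < rna_alpha) & ~rna["flagged"]]
    merged = atac[~atac["flagged"]].merge(
        sig, on="gene", suffixes=("_atac", "_rna"))
    if merged.empty:
        raise ValueError("no shared genes pass the RNA significance filter")
    r = float(np.corrcoef(merged["beta_d_atac"], merged["beta_d_rna"])[0, 1])
    concord = float(np.mean(np.sign(merged["beta_d_atac"])
                            == np.sign(merged["beta_d_rna"])))
    return {"table": merged, "pearson_r": r, "sign_concordance": concord,
            "n_genes": len(merged)}


@dataclass
class ViabilityFit:
    drug: str
    b: float
    c: float
    d: float
    e: float
    sse: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.c + (self.d - self.c) / (
            1.0 + np.exp(self.b * (np.log(x) - np.log(self.e))))


def fit_viability_4pl(counts, doses, drug: str = "") -> ViabilityFit:
    """Four-parameter log-logistic fit of cell recovery against dose.

    Vehicle (dose 0) points are excluded (ln 0 undefined); the upper
    asymptote absorbs the baseline. Nonlinear least squares on
    (b, c, d, ln e); non-convergence raises with the last parameter state.
    """
    counts = np.asarray(counts, dtype=float)
    doses = np.asarray(doses, dtype=float)
    pos = doses > 0
    x, y = doses[pos], counts[pos]
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct positive doses for a 4PL fit")

    def f(x, b, c, d, log_e):
        return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - log_e)))

    decreasing = y[np.argsort(x)][-1] < y[np.argsort(x)][0]
    p0 = [1.0 if decreasing else -1.0, float(y.min()), float(y.max()),
          float(np.log(np.median(x)))]
    try:
        popt, _ = optimize.curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit did not converge (started at {p0}): {exc}")
    b, c, d, log_e = popt
    resid = y - f(x, *popt)
    return ViabilityFit(drug=drug, b=float(b), c=float(c), d=float(d),
                        e=float(np.exp(log_e)), sse=float(resid @ resid))
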
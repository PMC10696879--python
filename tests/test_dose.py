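import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import hashatac as ha
from hashatac._stats import fit_logistic_wald, fit_quasipoisson
from hashatac.io import LabeledMatrix

from conftest import irls_glm


def design_frame(drug, dose, f=None, t=None):
    n = len(drug)
    df = pd.DataFrame({
        "cell": [f"c{i}" for i in range(n)],
        "drug": drug, "dose": dose,
        "f": np.full(n, np.log(3000.0)) if f is None else f,
        "t": np.full(n, 8.0) if t is None else t,
        "vehicle": np.asarray(dose) == 0,
    }).set_index("cell", drop=False)
    df.index.name = None
    return df


class TestSubset:
    def test_drug_plus_vehicle(self):
        d = design_frame(["A"] * 3 + ["B"] * 3 + ["vehicle"] * 2,
                         [1, 1, 1, 2, 2, 2, 0, 0])
        C = ha.subset_cells_for_drug(d, "A")
        assert set(C) == {"c0", "c1", "c2", "c6", "c7"}

    def test_unknown_drug(self):
        d = design_frame(["A", "vehicle"], [1, 0])
        with pytest.raises(ValueError, match="no treated cells"):
            ha.subset_cells_for_drug(d, "Z")

    def test_vehicle_only_design(self):
        d = design_frame(["vehicle"] * 3, [0, 0, 0])
        with pytest.raises(ValueError):
            ha.subset_cells_for_drug(d, "vehicle")


class TestLogDose:
    def test_delta_is_tenth_of_smallest_dose(self):
        d = ha.add_log_dose(design_frame(["A", "A", "vehicle"], [0.5, 5, 0]))
        assert d["log_dose_delta"].iloc[0] == pytest.approx(0.05)
        assert d.loc[d["dose"] == 0, "d"].iloc[0] == pytest.approx(
            np.log10(0.05))


class TestPeakDA:
    def saturated_matrix(self, n_per=200):
        # accessibility 0.2 at d=0 and 0.8 at d=1, covariates constant
        y = np.r_[np.repeat([1, 0], [int(0.2 * n_per), n_per
                                     - int(0.2 * n_per)]),
                  np.repeat([1, 0], [int(0.8 * n_per), n_per
                                     - int(0.8 * n_per)])]
        design = design_frame(["vehicle"] * n_per + ["A"] * n_per,
                              [0] * n_per + [9.0] * n_per)
        design["d"] = np.r_[np.zeros(n_per), np.ones(n_per)]
        m = LabeledMatrix(sp.csr_matrix(y.reshape(-1, 1)),
                          list(design["cell"]), ["peak0"])
        return m, design

    def test_saturated_two_group_log_odds_ratio(self):
        m, design = self.saturated_matrix()
        res = ha.run_peak_da(m, design, drug="A")
        assert res.loc[0, "beta_d"] == pytest.approx(np.log(16), abs=1e-6)

    def test_min_fraction_filter(self, dose_dataset):
        _, ds = dose_dataset
        res_all = ha.run_peak_da(ds.matrix, ds.design, min_frac=0.0)
        frac = res_all.set_index("peak")["accessible_fraction"]
        res = ha.run_peak_da(ds.matrix, ds.design, min_frac=0.01)
        excluded = set(frac.index[frac < 0.01])
        assert excluded.isdisjoint(res["peak"])
        assert len(res) == (frac >= 0.01).sum()

    def test_direction_follows_sign(self, dose_dataset):
        _, ds = dose_dataset
        res = ha.run_peak_da(ds.matrix, ds.design)
        assert ((res["beta_d"] > 0) == (res["direction"] == "opening")).all()

    def test_pooled_bh_equals_bh_on_concatenation(self):
        # two drugs analyzed jointly must share one BH family
        rng = np.random.default_rng(0)
        n = 150
        design = design_frame(
            ["A"] * n + ["B"] * n + ["vehicle"] * n,
            [1.0] * n + [1.0] * n + [0.0] * n,
            f=rng.normal(np.log(3000), 0.5, 3 * n),
            t=np.clip(rng.normal(8, 2, 3 * n), 0, None))
        X = (rng.random((3 * n, 30)) < 0.4).astype(np.int8)
        m = LabeledMatrix(sp.csr_matrix(X), list(design["cell"]),
                          [f"p{j}" for j in range(30)])
        res = ha.run_peak_da(m, design)
        ok = res["p"].notna()
        np.testing.assert_allclose(res.loc[ok, "padj"],
                                   ha.bh_adjust(res.loc[ok, "p"]))

    def test_planted_effect_recovery(self, dose_dataset):
        _, ds = dose_dataset
        res = ha.run_peak_da(ds.matrix, ds.design)
        merged = res.merge(ds.truth.beta_d.rename("true"), left_on="peak",
                           right_index=True)
        nz = merged[merged["true"] != 0]
        assert np.abs(nz["beta_d"] - nz["true"]).mean() <= 0.3
        assert nz["significant"].mean() >= 0.8

    def test_logistic_matches_irls_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(60, 150)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            beta = rng.normal(scale=0.8, size=4)
            y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
            if y.sum() in (0, n):
                continue
            res = fit_logistic_wald(y, X, coef_index=1)
            ref, cov = irls_glm(y, X, "binomial")
            assert res["beta"] == pytest.approx(ref[1], abs=1e-6)
            assert res["se"] == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-6)
            assert res["z"] == pytest.approx(ref[1] / np.sqrt(cov[1, 1]),
                                             abs=1e-6)


class TestGeneDoseModel:
    def two_group(self, mu0, mu1, n=300):
        y = np.r_[np.full(n, mu0), np.full(n, mu1)]
        design = design_frame(["vehicle"] * n + ["A"] * n,
                              [0] * n + [5.0] * n)
        design["d"] = np.r_[np.zeros(n), np.ones(n)]
        m = LabeledMatrix(sp.csr_matrix(y.reshape(-1, 1)),
                          list(design["cell"]), ["g0"])
        sf = pd.Series(1.0, index=design["cell"])
        return m, design, sf

    def test_two_group_closed_form(self):
        m, design, sf = self.two_group(2.0, 8.0)
        res = ha.fit_gene_dose_model(m, design, "A", sf)
        assert res.loc[0, "beta_d"] == pytest.approx(np.log(4), abs=1e-6)

    def test_size_factor_offset_invariance(self):
        m, design, sf = self.two_group(2.0, 8.0)
        r1 = ha.fit_gene_dose_model(m, design, "A", sf)
        r2 = ha.fit_gene_dose_model(m, design, "A", 2.0 * sf)
        assert r1.loc[0, "beta_d"] == pytest.approx(r2.loc[0, "beta_d"],
                                                    abs=1e-10)

    def test_all_zero_gene_flagged(self):
        m, design, sf = self.two_group(0.0, 0.0)
        res = ha.fit_gene_dose_model(m, design, "A", sf)
        assert bool(res.loc[0, "flagged"])

    def test_null_gene_coverage(self, dose_dataset):
        # planted-null genes: beta within +-3 SE of 0 in >= 95% of genes
        _, ds = dose_dataset
        rng = np.random.default_rng(5)
        n = len(ds.design)
        Y = rng.poisson(3.0, size=(n, 60))
        m = LabeledMatrix(sp.csr_matrix(Y), list(ds.design["cell"]),
                          [f"null{j}" for j in range(60)])
        sf = pd.Series(1.0, index=ds.design["cell"])
        res = ha.fit_gene_dose_model(m, ds.design, "drugA", sf)
        cover = (np.abs(res["beta_d"]) <= 3 * res["se"]).mean()
        assert cover >= 0.95

    def test_quasipoisson_matches_irls_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(50, 120)
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            off = rng.normal(scale=0.1, size=n)
            y = rng.poisson(np.exp(0.5 + 0.4 * X[:, 1] + off))
            if y.sum() == 0:
                continue
            res = fit_quasipoisson(y, X, coef_index=1, offset=off)
            ref, cov = irls_glm(y, X, "poisson", offset=off)
            assert res["beta"] == pytest.approx(ref[1], abs=1e-6)
            mu = np.exp(X @ ref + off)
            phi = np.sum((y - mu) ** 2 / mu) / (n - 2)
            assert res["se"] == pytest.approx(
                np.sqrt(phi * cov[1, 1]), rel=1e-6)


class TestCompareCoeffs:
    def test_identical_vectors_correlate_perfectly(self):
        atac = pd.DataFrame({"gene": list("abc"), "beta_d": [1, 2, 3.0],
                             "flagged": False})
        rna = atac.assign(padj=0.01)
        out = ha.compare_atac_rna_coeffs(atac, rna)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["sign_concordance"] == 1.0

    def test_disjoint_genes_error(self):
        atac = pd.DataFrame({"gene": ["a"], "beta_d": [1.0],
                             "flagged": False})
        rna = pd.DataFrame({"gene": ["b"], "beta_d": [1.0], "padj": [0.01],
                            "flagged": False})
        with pytest.raises(ValueError, match="shared genes"):
            ha.compare_atac_rna_coeffs(atac, rna)

    def test_attenuated_recovery_on_simulation(self, dose_dataset):
        _, ds = dose_dataset
        rna = ha.fit_gene_dose_model(ds.rna, ds.design, "drugA",
                                     ds.size_factors)
        atac = ha.fit_gene_dose_model(ds.gene_score, ds.design, "drugA",
                                      ds.size_factors)
        out = ha.compare_atac_rna_coeffs(atac, rna)
        assert out["pearson_r"] > 0.8


class TestViability4PL:
    def test_noiseless_recovery(self):
        doses = np.array([0.1, 0.5, 1, 5, 10, 50.0])
        b, c, d, e = 1.0, 0.0, 100.0, 10.0
        y = c + (d - c) / (1 + np.exp(b * (np.log(doses) - np.log(e))))
        fit = ha.fit_viability_4pl(y, doses)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-4)
        assert fit.d == pytest.approx(d, rel=1e-6)
        assert fit.e == pytest.approx(e, rel=1e-6)

    def test_midpoint_identity(self):
        doses = np.array([0.1, 1, 3, 10, 100.0])
        y = 5 + 80 / (1 + np.exp(0.8 * (np.log(doses) - np.log(3.0))))
        fit = ha.fit_viability_4pl(y, doses)
        assert fit.predict(fit.e) == pytest.approx((fit.c + fit.d) / 2,
                                                   rel=1e-6)

    def test_decreasing_data_has_positive_steepness(self):
        rng = np.random.default_rng(0)
        doses = np.array([0.1, 0.3, 1, 3, 10, 30.0])
        y = 100 / (1 + np.exp(1.2 * (np.log(doses) - np.log(2))))
        y = y + rng.normal(0, 1, size=len(y))
        fit = ha.fit_viability_4pl(y, doses)
        assert fit.b > 0

    def test_vehicle_excluded_and_min_doses(self):
        with pytest.raises(ValueError, match="4 distinct"):
            ha.fit_viability_4pl([5, 4, 3], [0.0, 1.0, 10.0])
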
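"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here: hash-oligo UMI
count matrices over an ambient background (with debris barcodes and planted
doublets), species-mixing fragment tallies, dose-dependent binary peak
accessibility with nuisance covariates, motif/gene/RNA matrices with
planted distal-motif expression effects, and a 1-D latent trajectory with
opening/closing/dynamic peaks and a FRIP-dose interaction.

The generative models are the inverses of the fitted models downstream:
accessibility is Bernoulli on a logit-linear predictor in log-dose and QC
covariates, RNA counts are Poisson with log-mean linear in log-dose, hash
counts are multinomial mixtures of a sample's own hash and a Dirichlet
ambient profile. Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .io import LabeledMatrix

__all__ = [
    "SimConfig", "GroundTruth", "simulate_hash_experiment",
    "simulate_species_mix", "simulate_dose_response_dataset",
    "simulate_trajectory_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults describe a small hashed chemical-screen plate: 2000 nuclei from
    8 wells, ~200 hash UMIs per nucleus of which ~7.5% are ambient (about a
    100-fold enrichment of the true label over any other hash), 10%
    doublets, 200 fixed-width peaks, a 4-dose titration plus vehicle.
    """

    n_cells: int = 2000
    n_samples: int = 8
    n_hashes: int = 8
    mean_hash_umis: float = 200.0
    hash_dispersion: float = 5.0
    background_fraction: float = 0.075
    doublet_rate: float = 0.10
    debris_factor: float = 5.0
    ambient_concentration: float = 1.0
    n_features: int = 200
    n_doses: int = 4
    dose_levels: tuple = (0.01, 0.1, 1.0, 10.0)
    effect_sizes: tuple | None = None
    trajectory_fraction_opening: float = 0.3
    trajectory_fraction_closing: float = 0.3
    trajectory_fraction_dynamic: float = 0.2
    frip_dose_interaction: float = 0.05
    n_genes: int = 100
    n_motifs: int = 25
    drugs: tuple = ("drugA",)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells", "n_samples", "n_hashes", "n_features",
                     "n_doses", "n_genes", "n_motifs"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("background_fraction", "doublet_rate",
                     "trajectory_fraction_opening",
                     "trajectory_fraction_closing",
                     "trajectory_fraction_dynamic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_hashes < self.n_samples:
            raise ValueError("n_hashes must be >= n_samples")
        if self.mean_hash_umis <= 0:
            raise ValueError("mean_hash_umis must be positive")
        doses = np.asarray(self.dose_levels, dtype=float)
        if len(doses) != self.n_doses:
            raise ValueError("dose_levels length must equal n_doses")
        if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ValueError("dose_levels must be strictly increasing and positive")
        tf = (self.trajectory_fraction_opening + self.trajectory_fraction_closing
              + self.trajectory_fraction_dynamic)
        if tf > 1.0 + 1e-12:
            raise ValueError("trajectory fractions must sum to <= 1")
        if self.effect_sizes is not None and len(self.effect_sizes) != self.n_features:
            raise ValueError("effect_sizes length must equal n_features")


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset (fields filled as relevant)."""

    labels: pd.Series | None = None            # cell -> true sample label
    doublet_type: pd.Series | None = None      # singlet / heterotypic / homotypic
    doublet_partners: dict = field(default_factory=dict)
    debris_barcodes: list = field(default_factory=list)
    pseudodose: pd.Series | None = None        # cell -> true latent position
    trend_class: pd.Series | None = None       # feature -> trend class
    beta_d: pd.Series | None = None            # feature -> true dose coefficient
    gene_beta_d: pd.Series | None = None       # gene -> true RNA dose coefficient
    motif_effects: pd.Series | None = None     # motif -> distal expression effect
    promoter_motif_effects: pd.Series | None = None
    species: pd.Series | None = None
    is_collision: pd.Series | None = None


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def _nb_totals(rng, n, mean, size):
    p = size / (size + mean)
    return np.maximum(rng.negative_binomial(size, p, size=n), 1)


def _ambient_profile(config: SimConfig, rng) -> np.ndarray:
    return rng.dirichlet(np.full(config.n_hashes,
                                 config.ambient_concentration))


def simulate_hash_experiment(config: SimConfig):
    """Simulate a hashed plate: (HashCountMatrix, GroundTruth).

    The returned matrix stacks real-cell rows over debris rows; debris
    barcodes (named ``debris####``) draw purely from the ambient profile at
    low depth and are listed in ``truth.debris_barcodes``.
    """
    rng = _rng(config, 1)
    n, k = config.n_cells, config.n_hashes
    ambient = _ambient_profile(config, rng)
    sample_hash = np.arange(config.n_samples) % k  # sample -> its hash index

    cells = [f"cell{i:05d}" for i in range(n)]
    is_doublet = rng.random(n) < config.doublet_rate
    s1 = rng.integers(0, config.n_samples, size=n)
    s2 = rng.integers(0, config.n_samples, size=n)

    def singlet_counts(sample):
        total = _nb_totals(rng, 1, config.mean_hash_umis,
                           config.hash_dispersion)[0]
        p = config.background_fraction * ambient.copy()
        p[sample_hash[sample]] += 1.0 - config.background_fraction
        return rng.multinomial(total, p)

    counts = np.zeros((n, k), dtype=np.int64)
    dtypes, partners, labels = [], {}, []
    for i in range(n):
        if is_doublet[i]:
            counts[i] = singlet_counts(s1[i]) + singlet_counts(s2[i])
            kind = "homotypic" if s1[i] == s2[i] else "heterotypic"
            dtypes.append(kind)
            partners[cells[i]] = (f"sample{s1[i]}", f"sample{s2[i]}")
        else:
            counts[i] = singlet_counts(s1[i])
            dtypes.append("singlet")
        labels.append(f"sample{s1[i]}")

    n_debris = int(round(config.debris_factor * n))
    debris_names = [f"debris{i:05d}" for i in range(n_debris)]
    debris_totals = rng.poisson(5.0, size=n_debris)
    debris = np.vstack([rng.multinomial(t, ambient) for t in debris_totals]) \
        if n_debris else np.zeros((0, k), dtype=np.int64)

    matrix = LabeledMatrix(
        sp.csr_matrix(np.vstack([counts, debris])),
        cells + debris_names,
        [f"hash{j}" for j in range(k)],
    )
    truth = GroundTruth(
        labels=pd.Series(labels, index=cells),
        doublet_type=pd.Series(dtypes, index=cells),
        doublet_partners=partners,
        debris_barcodes=debris_names,
    )
    return matrix, truth


def simulate_species_mix(config: SimConfig, purity_alpha: float = 200.0):
    """Two-species (human/mouse) mixing experiment with planted collisions.

    Samples are split evenly between species; collision barcodes combine the
    chromatin and hash counts of two cells from opposite species, so the
    planted collision rate is the expected chromatin-detectable mixed-species
    rate. Returns (table, hash_counts: LabeledMatrix, truth).
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2 for a species mix")
    rng = _rng(config, 2)
    n = config.n_cells
    half = config.n_samples // 2
    ambient = _ambient_profile(config, rng)
    sample_hash = np.arange(config.n_samples) % config.n_hashes

    cells = [f"cell{i:05d}" for i in range(n)]
    is_coll = rng.random(n) < config.doublet_rate

    def draw_cell(sample):
        total = int(np.round(np.exp(rng.normal(np.log(3000), 0.5))))
        own = rng.beta(purity_alpha, purity_alpha * (1 - 0.97) / 0.97)
        species = "human" if sample < half else "mouse"
        h = int(np.round(total * own)) if species == "human" else \
            int(np.round(total * (1 - own)))
        m = total - h
        t = _nb_totals(rng, 1, config.mean_hash_umis, config.hash_dispersion)[0]
        p = config.background_fraction * ambient.copy()
        p[sample_hash[sample]] += 1 - config.background_fraction
        return h, m, rng.multinomial(t, p), species

    rows, hashes, species_l, labels = [], [], [], []
    for i in range(n):
        s1 = rng.integers(0, half)
        if is_coll[i]:
            s2 = rng.integers(half, config.n_samples)
            h1, m1, c1, _ = draw_cell(s1)
            h2, m2, c2, _ = draw_cell(s2)
            rows.append((h1 + h2, m1 + m2))
            hashes.append(c1 + c2)
            species_l.append("mixed")
        else:
            s = rng.integers(0, config.n_samples)
            s1 = s
            h, m, c, spc = draw_cell(s)
            rows.append((h, m))
            hashes.append(c)
            species_l.append(spc)
        labels.append(f"sample{s1}")

    table = pd.DataFrame(rows, columns=["human_frags", "mouse_frags"],
                         index=cells)
    n_debris = int(round(config.debris_factor * n))
    debris_names = [f"debris{i:05d}" for i in range(n_debris)]
    debris_totals = rng.poisson(5.0, size=n_debris)
    debris = np.vstack([rng.multinomial(t, ambient) for t in debris_totals]) \
        if n_debris else np.zeros((0, config.n_hashes), dtype=np.int64)
    hash_counts = LabeledMatrix(
        sp.csr_matrix(np.vstack([np.vstack(hashes), debris])),
        cells + debris_names,
        [f"hash{j}" for j in range(config.n_hashes)])
    truth = GroundTruth(
        labels=pd.Series(labels, index=cells),
        species=pd.Series(species_l, index=cells),
        is_collision=pd.Series(is_coll, index=cells),
        debris_barcodes=debris_names,
    )
    return table, hash_counts, truth


def _dose_design(config: SimConfig, rng, vehicle_fraction=0.2):
    """Assign cells to drug/dose; draw QC covariates f (ln frags) and t (TSS)."""
    n = config.n_cells
    cells = [f"cell{i:05d}" for i in range(n)]
    n_vehicle = int(round(vehicle_fraction * n))
    drug = np.array(["vehicle"] * n, dtype=object)
    dose = np.zeros(n)
    treated = np.arange(n_vehicle, n)
    drug[treated] = [config.drugs[i % len(config.drugs)] for i in
                     range(len(treated))]
    doses = np.asarray(config.dose_levels, float)
    dose[treated] = doses[np.arange(len(treated)) % len(doses)]
    delta = doses.min() / 10.0
    f = rng.normal(np.log(3000), 0.5, size=n)
    t = np.clip(rng.normal(8.0, 2.0, size=n), 0.0, None)
    design = pd.DataFrame({
        "cell": cells, "drug": drug, "dose": dose,
        "d": np.log10(dose + delta),
        "f": f, "t": t,
        "replicate": rng.integers(1, 3, size=n),
        "vehicle": dose == 0,
    }).set_index("cell", drop=False)
    design.index.name = None
    return design, delta


def _default_effect_sizes(config: SimConfig) -> np.ndarray:
    k = config.n_features
    beta = np.zeros(k)
    third = k // 3
    beta[:third] = 2.0
    beta[third:2 * third] = -2.0
    return beta


@dataclass
class DoseResponseDataset:
    """Bundle of inputs for the dose-response / motif / expression stages."""

    matrix: LabeledMatrix          # binary cells x peaks
    design: pd.DataFrame
    motifs: LabeledMatrix          # binary peaks x motifs
    gene_score: LabeledMatrix      # cells x genes (counts)
    rna: LabeledMatrix             # cells x genes (counts)
    size_factors: pd.Series
    links: pd.DataFrame            # peak_a, peak_b, score
    peaks: pd.DataFrame            # BED
    tss: pd.DataFrame              # BED (1-bp TSS) with gene names
    truth: GroundTruth
    log_dose_delta: float


def simulate_dose_response_dataset(config: SimConfig) -> DoseResponseDataset:
    """Binary peak accessibility responding to log-dose, plus RNA/motif layers.

    Peak accessibility: Y ~ Bernoulli(expit(b0 + bd*d + bf*(f - ln3000)
    + bt*(t - 8))) with bf=0.25, bt=0.05 and planted bd from
    ``config.effect_sizes`` (default: thirds at +2 / -2 / 0). RNA counts are
    Poisson with log-mean linear in d; each gene's dose coefficient is a
    baseline draw plus planted contributions from driver motifs acting
    through distal co-accessibility links with score >= 0.1.
    """
    rng = _rng(config, 3)
    design, delta = _dose_design(config, rng)
    n, k = config.n_cells, config.n_features
    beta_d = (np.asarray(config.effect_sizes, float)
              if config.effect_sizes is not None
              else _default_effect_sizes(config))
    if len(beta_d) != k:
        raise ValueError("effect_sizes length must equal n_features")

    beta0 = rng.normal(-1.0, 0.7, size=k)
    eta = (beta0[None, :] + np.outer(design["d"], beta_d)
           + 0.25 * (design["f"].to_numpy() - np.log(3000))[:, None]
           + 0.05 * (design["t"].to_numpy() - 8.0)[:, None])
    acc = (rng.random((n, k)) < expit(eta)).astype(np.int8)

    peak_names = [f"peak{j:04d}" for j in range(k)]
    peaks = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(k) * 2000,
        "end": np.arange(k) * 2000 + 500,
        "name": peak_names,
    })
    motifs = LabeledMatrix(
        sp.csr_matrix((rng.random((k, config.n_motifs)) < 0.1).astype(np.int8)),
        peak_names, [f"motif{m:02d}" for m in range(config.n_motifs)])

    # genes: gene g's promoter is peak g (TSS at peak start); the rest are distal
    n_genes = min(config.n_genes, k)
    gene_names = [f"gene{g:03d}" for g in range(n_genes)]
    tss = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_genes) * 2000,
        "end": np.arange(n_genes) * 2000 + 1,
        "name": gene_names,
    })
    distal = np.arange(n_genes, k)
    link_rows = []
    for g in range(n_genes):
        if len(distal) == 0:
            break
        for pb in rng.choice(distal, size=min(3, len(distal)), replace=False):
            link_rows.append((peak_names[g], peak_names[pb],
                              float(np.round(rng.random(), 6))))
    links = pd.DataFrame(link_rows, columns=["peak_a", "peak_b", "score"])

    # planted motif -> expression effects: distal drivers act through
    # thresholded co-accessibility links, promoter drivers through motif
    # presence in the gene's promoter peak
    n_driver = min(3, config.n_motifs)
    perm = rng.choice(config.n_motifs, size=min(5, config.n_motifs),
                      replace=False)
    driver_idx, prom_idx = perm[:n_driver], perm[n_driver:]
    driver_eff = np.array([1.0, -0.8, 0.6])[:n_driver]
    prom_eff = np.array([0.8, -0.6])[:len(prom_idx)]
    motif_eff = pd.Series(0.0, index=motifs.col_names)
    motif_eff.iloc[driver_idx] = driver_eff
    promoter_motif_eff = pd.Series(0.0, index=motifs.col_names)
    promoter_motif_eff.iloc[prom_idx] = prom_eff
    M = motifs.matrix.toarray()
    gene_bd = rng.normal(0.0, 0.2, size=n_genes)
    pk_index = {p: i for i, p in enumerate(peak_names)}
    for g, gene in enumerate(gene_names):
        gene_bd[g] += float(M[g, prom_idx] @ prom_eff) if len(prom_idx) else 0.0
        sub = links[(links["peak_a"] == peak_names[g]) & (links["score"] >= 0.1)]
        for mi, eff in zip(driver_idx, driver_eff):
            best = 0.0
            for _, row in sub.iterrows():
                if M[pk_index[row["peak_b"]], mi]:
                    best = max(best, row["score"])
            gene_bd[g] += eff * best

    size_factors = pd.Series(np.exp(rng.normal(0, 0.2, size=n)),
                             index=design["cell"])
    gamma0 = rng.normal(np.log(3.0), 0.3, size=n_genes)
    mu_rna = size_factors.to_numpy()[:, None] * np.exp(
        gamma0[None, :] + np.outer(design["d"], gene_bd))
    rna = rng.poisson(mu_rna)
    # gene activity as seen by ATAC: attenuated dose effect, own noise
    mu_gs = size_factors.to_numpy()[:, None] * np.exp(
        gamma0[None, :] + np.outer(design["d"], 0.6 * gene_bd)
        + rng.normal(0, 0.05, size=(n, n_genes)))
    gene_score = rng.poisson(mu_gs)

    truth = GroundTruth(
        beta_d=pd.Series(beta_d, index=peak_names),
        gene_beta_d=pd.Series(gene_bd, index=gene_names),
        motif_effects=motif_eff,
        promoter_motif_effects=promoter_motif_eff,
    )
    cells = list(design["cell"])
    return DoseResponseDataset(
        matrix=LabeledMatrix(sp.csr_matrix(acc), cells, peak_names),
        design=design,
        motifs=motifs,
        gene_score=LabeledMatrix(sp.csr_matrix(gene_score), cells, gene_names),
        rna=LabeledMatrix(sp.csr_matrix(rna), cells, gene_names),
        size_factors=size_factors,
        links=links, peaks=peaks, tss=tss, truth=truth,
        log_dose_delta=delta,
    )


@dataclass
class TrajectoryDataset:
    matrix: LabeledMatrix
    design: pd.DataFrame
    psi_true: pd.Series
    fragments: pd.Series
    frip: pd.Series
    truth: GroundTruth


def simulate_trajectory_dataset(config: SimConfig) -> TrajectoryDataset:
    """Cells on a 1-D latent axis psi* in [0,1] correlated with dose.

    Opening features gain accessibility along psi*, closing features lose it,
    dynamic features peak mid-trajectory; the remainder are static. FRIP is
    Gaussian around base + frip_dose_interaction * psi* * d.
    """
    rng = _rng(config, 4)
    design, _ = _dose_design(config, rng)
    n, k = config.n_cells, config.n_features
    dose_rank = design["dose"].rank(method="dense") - 1
    dose_rank = dose_rank / max(dose_rank.max(), 1)
    psi = np.clip(dose_rank.to_numpy() * 0.85
                  + rng.normal(0, 0.08, size=n), 0.0, 1.0)

    n_open = int(round(config.trajectory_fraction_opening * k))
    n_close = int(round(config.trajectory_fraction_closing * k))
    n_dyn = int(round(config.trajectory_fraction_dynamic * k))
    classes = np.array(
        ["opening"] * n_open + ["closing"] * n_close + ["dynamic"] * n_dyn
        + ["static"] * (k - n_open - n_close - n_dyn))

    eta = np.empty((n, k))
    span = 5.0
    for j, cls in enumerate(classes):
        if cls == "opening":
            eta[:, j] = -2.5 + span * psi
        elif cls == "closing":
            eta[:, j] = 2.5 - span * psi
        elif cls == "dynamic":
            eta[:, j] = -2.5 + span * np.exp(-(psi - 0.5) ** 2 / (2 * 0.12 ** 2))
        else:
            eta[:, j] = -1.0
    acc = (rng.random((n, k)) < expit(eta)).astype(np.int8)

    cells = list(design["cell"])
    frags = pd.Series(np.round(np.exp(design["f"])).astype(int).to_numpy(),
                      index=cells, name="fragments")
    frip = pd.Series(np.clip(
        0.5 + config.frip_dose_interaction * psi * design["d"].to_numpy()
        + rng.normal(0, 0.04, size=n), 0.0, 1.0), index=cells, name="frip")

    peak_names = [f"peak{j:04d}" for j in range(k)]
    truth = GroundTruth(
        pseudodose=pd.Series(psi, index=cells),
        trend_class=pd.Series(classes, index=peak_names),
    )
    return TrajectoryDataset(
        matrix=LabeledMatrix(sp.csr_matrix(acc), cells, peak_names),
        design=design, psi_true=truth.pseudodose,
        fragments=frags, frip=frip, truth=truth,
    )
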
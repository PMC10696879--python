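# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Hash demultiplexing

Each nucleus i carries a vector **h**ᵢ of hash UMI counts over the K hash
oligos used in the experiment. Barcodes below the chromatin fragment
threshold ("debris") are assumed to sample only ambient hash molecules;
their mean count vector, normalized to proportions, is the background
profile. For each nucleus we compute a one-sample chi-squared
goodness-of-fit statistic Σ(obs − exp)²/exp against that background with
exp = proportion × total UMIs, df = (#categories) − 1, and an upper-tail
p-value. Hashes with zero background proportion but nonzero observed counts
are pooled into one extra category with a vanishing expected mass, so the
statistic stays finite and such cells flag as strongly enriched. No
continuity correction or small-expected-count adjustment is applied. BH
adjustment is computed across all cells tested in one run.

The enrichment score is the ratio of the most to second-most abundant hash;
a nucleus with exactly one observed hash scores its own count (avoiding
infinities). Calls: singlet requires total UMIs ≥ 10, adjusted p < 0.05,
and enrichment ≥ α (α floored at 2); enriched nuclei with low enrichment
are multiplets; everything else is unassigned. Ties for the top hash are
broken deterministically by hash id, and a tie forces enrichment 1, i.e. a
multiplet — the conservative reading.

Species-mixing evaluation: a barcode is a chromatin collision when strictly
less than 90% of its fragments map to one species; the report cross-tabulates
chromatin collisions against hash multiplet calls and measures label
accuracy on chromatin singlets.

## QC, binarization, TF-IDF/LSI

Fragments use 0-based half-open (BED) coordinates throughout. FRIP is the
count-weighted fraction of a cell's fragments overlapping peaks. TSS
enrichment is the per-base Tn5 insertion rate (both fragment ends) in
TSS ± 50 bp over the rate in 100-bp flanks centered ± 1950 bp, aggregated
over TSSs — a deliberately simple stand-in for tool-specific definitions;
only its role as a filter covariate and model covariate matters here. QC
thresholds (≥ 500 fragments, TSS ≥ 3) are inclusive; barcodes below the
fragment threshold form the debris set that feeds background estimation.

The binary matrix sets 1 when ≥ 1 fragment overlaps a feature; features
open in < 0.5% of cells are dropped (1% within per-drug DA subsets). The
TF-IDF transform is ln(1 + 10⁴·TF)·ln(IDF) with TF the row-normalized
entry and IDF = N/column-sum; raw ln(TF) is undefined at zero, hence the
scaled log1p, while ln(IDF) is left unshifted so ubiquitous features vanish
exactly. Truncated SVD (default 50 components) uses a fixed ARPACK starting
vector and a sign convention (largest-magnitude loading positive) for
reproducibility; the first component, which tracks depth, can be dropped.

## Doublet detection

Doublets are simulated as element-wise ORs of random pairs of distinct
cells (default: as many simulated as observed). The IDF is derived from
observed cells only; the SVD basis is fit on observed cells and simulated
profiles are projected onto it — projection keeps the observed geometry
fixed; a joint-basis option exists. Scores are the fraction of simulated
doublets among a cell's k nearest neighbors (Euclidean, 49 dimensions
after dropping the first component; k = round(0.5·√(n_obs + n_sim)) by the
classic scrublet heuristic). The top 10% of cells by score are pruned,
exactly ⌈0.1·n⌉, ties at the cutoff broken by barcode order.

## Dose-response models

For drug D the cell set C is all D-treated plus all vehicle cells. Doses
enter as d = log₁₀(dose + δ) with δ = (smallest nonzero dose)/10, so
vehicle is a finite low value; δ is recorded. Peaks accessible in ≥ 1% of
C are fit with logistic IRLS on (d, f, t); zero-variance covariates are
dropped automatically (saturated designs stay estimable). Fits whose
coefficients exceed 15 in magnitude are flagged as separated and excluded
from the significant set. Raw Wald p-values are pooled across all drugs
and peaks before one BH pass; DA means adjusted p < 0.05.

Gene-level models are quasipoisson (Poisson IRLS, Pearson-scale dispersion)
with ln(size factor) offsets. The viability curve is the four-parameter
log-logistic f(x) = c + (d−c)/(1 + exp(b(ln x − ln e))) fit by nonlinear
least squares on (b, c, d, ln e); vehicle points are excluded (ln 0), the
upper asymptote absorbing the baseline. f(e) = (c+d)/2 by construction.

## Pseudodose trajectories

Graph learning is delegated in spirit to external tools; the stand-in here
is k-means (default 25 centroids) joined by a Euclidean minimum spanning
tree, which preserves the only two properties downstream math uses:
cell-to-node assignment and geodesic distances. An externally learned
node/edge table can be substituted. Roots are nodes whose assigned cells
are strictly majority vehicle; ψ is the shortest-path distance to the
nearest root, so ψ is invariant to rigid rotations of the embedding. Cells
are binned by 1-D k-means (k = 10) on ψ and receive their bin mean ψ̃.

For smoothing, bins with < 50 cells are merged into the adjacent bin, then
each bin is chunked contiguously by ψ into the finest split keeping every
group ≥ 50 cells (sizes thus fall in [50, 100]; a lone under-50 remainder
can only occur when the whole dataset is one deficient bin). Per peak, the
accessible-cell count A over groups is fit by a negative-binomial log-link
regression on natural splines (df = 3) of ψ̃ and of the group mean
accessible-feature count S̃, with ln(group size) as exposure offset —
group sizes vary within [50, 100] and without the offset count dips track
group size rather than accessibility. NB dispersion is estimated by
iterating a Pearson moment estimator around fixed-dispersion GLM fits
(Poisson start, floor 1e-8); non-convergent peaks fall back to Poisson with
a flag. Natural spline bases use the classical construction (boundary knots
at the data range, interior knots at quantiles, truncated-power form,
linear beyond the boundaries), built in-house because available basis
implementations are constant-inclusive and would make intercepted designs
singular; knots are stored and reused for prediction.

Fitted per-cell rates are evaluated at the observed groups and interpolated
onto 100 equally spaced ψ̃ bins — i.e. predictions keep each group's own
S̃ rather than freezing S̃ at its mean, matching frameworks that return
model predictions at the data rows. Classification: maximum in bins 1–20 →
closing, 81–100 → opening, otherwise dynamic; peaks that were not DA are
static.

FRIP dose dependence: full model FRIP ~ 1 + ns(ψ̃, 3) + ns(ψ̃, 3)·d
(Gaussian), reduced model drops the interaction columns; LRT statistic
2·Δll against chi-squared with df = 3. The spline main effects are kept in
the full model so the pair is properly nested; a model with only the
product term would not nest the reduced one.

## Motif and expression models

Trend enrichment: one univariate logistic regression per motif of class
membership on motif presence, two-tailed Wald z, BH within each
(trend × condition) family; motifs present in all or no peaks are skipped
as inestimable. Enriched = adjusted p < 0.05 with positive coefficient.

Gene features: a gene needs an accessible promoter peak (interval within
500 bp of the TSS base, inclusive — a peak 501 bp away does not count).
Promoter features are binary motif indicators over promoter peaks; the
distal feature per motif is the highest co-accessibility score (≥ 0.1 to
count as connected; links treated as undirected) from a promoter peak to a
motif-bearing linked distal peak, else 0. Targets are the per-gene RNA
dose coefficients of genes whose dose term is significant (adjusted
p < 0.05). Elastic net uses mixing 0.5 with penalty strength chosen by
5-fold cross-validation at a fixed seed; variance explained is training R²
at the selected penalty (a single explained-variance number per model),
and the fold increase is R²(promoter+distal)/R²(promoter).

## Synthetic data generator

The generator emits every input the pipeline reads, with ground truth.

* **Hash counts**: per-cell totals are negative binomial (mean 200,
  size 5); the ambient profile is a Dirichlet draw (concentration 1) over
  hashes; a singlet's counts are multinomial over
  (1 − b)·own-hash + b·ambient with b = 0.075, i.e. roughly 100-fold
  enrichment of the true label. Doublets (rate 0.10) sum two singlet draws
  — heterotypic when the two wells differ. Debris barcodes number 5× the
  cells at ~5 UMIs each, drawn purely from the ambient profile.
* **Species mixing**: wells split evenly between human and mouse; singlet
  species purity is Beta-distributed with mean 0.97 and concentration 200
  (sd ≈ 1%), so genuinely mixed barcodes are separable at the 90% rule;
  collisions combine one cell of each species, making the planted collision
  rate the expected chromatin-detectable rate.
* **Dose response**: 20% vehicle cells, the rest cycled over drugs × doses
  (0.01–10 µM); covariates f ~ N(ln 3000, 0.5²), t ~ N(8, 2²) truncated at
  0; accessibility is Bernoulli on β₀ + β_d·d + 0.25(f − ln 3000)
  + 0.05(t − 8) with planted β_d of +2/−2/0 in thirds. RNA counts are
  Poisson with log-mean linear in d and lognormal size factors; each
  gene's dose coefficient is a N(0, 0.2²) baseline plus planted
  contributions from three distal driver motifs acting through exactly the
  thresholded max-link-score feature the model later builds, and two
  promoter driver motifs acting through promoter presence (so both model
  variants have signal and the fold increase is finite). The gene-activity
  (ATAC) layer carries the same effects attenuated by 0.6.
* **Trajectory**: the latent position ψ* ∈ [0, 1] is the dose rank scaled
  by 0.85 plus N(0, 0.08²) noise, clipped — dose-correlated but noisy, as
  trajectories are. Opening features follow logit⁻¹(−2.5 + 5ψ*), closing
  the mirror image, dynamic a Gaussian bump at ψ* = 0.5 (σ = 0.12), static
  a constant; fractions 0.3/0.3/0.2/0.2. FRIP is
  0.5 + γ·ψ*·d + N(0, 0.04²) with γ = 0.05 by default.

What the generator does **not** emulate: read-level errors, fragment-length
and Tn5 insertion-sequence biases, peak-calling uncertainty, batch effects,
doublet-rate dependence on loading, mixture ambient profiles that vary by
plate position, branching trajectories, or realistic genome coordinates
(features are evenly spaced intervals on one contig). Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability under the stated generative assumptions, not robustness to
every artifact of real libraries.

## Problem sizes and determinism

Default simulated experiments use 2000 cells, 8 wells, 200 features, 100
genes, 25 motifs — sizes at which every planted effect is comfortably
identifiable and the full suite runs in well under a minute per stage on
one CPU. Calibration checks use 500–600 independent null tests (null peaks
share a design but draw independent Bernoulli responses, so they are
independent replications of the null) and 50 power replicates. All
generators and estimators take explicit seeds; identical seed + config is
bit-identical. GLM fits use IRLS tolerances of 1e-12; oracle-equivalence
tests compare against independent textbook IRLS implementations at 1e-6 on
coefficients and 1e-10 on test statistics.

## Known limitations

* The TSS enrichment definition is a documented simplification; absolute
  values are not comparable to other tools' scores.
* The principal-graph stand-in does not learn curved principal graphs; on
  strongly nonlinear embeddings geodesics are only as good as the
  centroid resolution (default 25).
* NB dispersion by moment iteration is less efficient than full ML when
  groups are few; with < ~10 groups dispersion is effectively unidentified
  and the fit approaches Poisson.
* BH families follow the stated conventions (all cells per demux run; all
  drugs × peaks per DA run; per trend × condition for motifs); other
  partitions would change adjusted values.
* The elastic-net "variance explained" is training R² at a CV-chosen
  penalty; an external-validation estimate would be smaller.
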
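"""Pseudodose trajectories and downstream smoothing/classification.

The principal graph is a documented stand-in for external graph-learning
tools: k-means centroids joined by a minimum spanning tree, preserving the
two properties downstream math uses (cell-to-node assignment and geodesic
distances). Root nodes are those whose assigned cells are majority
vehicle-treated; a cell's pseudodose psi is the shortest-path distance from
its node to the nearest root. Cells are binned by 1-D k-means (k=10) on
psi and each cell receives its bin mean. For trend smoothing, cells are
subdivided into contiguous-by-psi groups of 50-100 cells; per-peak
accessible-cell counts are modeled with a negative-binomial log-link
regression on natural splines of the group pseudodose and of overall
cell-wise accessibility, predictions are evaluated on a 100-bin grid, and
peaks are classified closing/opening/dynamic by whether the prediction
argmax falls in the first 20, last 20, or intervening bins (static if the
peak was not differentially accessible). FRIP dose dependence along the
trajectory is a Gaussian LRT of spline(psi)*dose interaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from ._stats import fit_negative_binomial, gaussian_lrt, natural_spline_basis
from .io import LabeledMatrix

__all__ = [
    "PrincipalGraph", "learn_principal_graph", "compute_pseudodose",
    "PrincipalGraphTrajectory", "AggregateAccessibility", "aggregate_groups",
    "smooth_and_classify", "fit_frip_interaction",
]


@dataclass
class PrincipalGraph:
    nodes: np.ndarray                 # centroid coordinates
    graph: nx.Graph                   # MST with Euclidean edge weights
    assignment: np.ndarray            # cell -> node index
    root_nodes: list = field(default_factory=list)


def learn_principal_graph(embedding, n_centroids: int = 25, seed: int = 0
                          ) -> PrincipalGraph:
    """k-means centroids joined by their Euclidean minimum spanning tree."""
    X = np.asarray(embedding, dtype=float)
    if n_centroids < 2 or n_centroids > len(X):
        raise ValueError("n_centroids must be in [2, n_cells]")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate embedding: all points identical")
    km = KMeans(n_clusters=n_centroids, random_state=seed, n_init=10).fit(X)
    centers = km.cluster_centers_
    D = squareform(pdist(centers))
    mst = minimum_spanning_tree(D).toarray()
    g = nx.Graph()
    g.add_nodes_from(range(len(centers)))
    for i, j in zip(*np.nonzero(mst)):
        g.add_edge(int(i), int(j), weight=float(D[i, j]))
    return PrincipalGraph(nodes=centers, graph=g, assignment=km.labels_)


def compute_pseudodose(graph: PrincipalGraph, vehicle, k_bins: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """Geodesic pseudodose from majority-vehicle root nodes, k-means binned.

    ``vehicle`` is a boolean array over cells (aligned with the graph's
    assignment). Returns a frame with psi, bin id (ordered by bin mean) and
    the bin-mean pseudodose assigned to every cell in the bin.
    """
    vehicle = np.asarray(vehicle, dtype=bool)
    roots = []
    for node in graph.graph.nodes:
        mask = graph.assignment == node
        if mask.any() and vehicle[mask].mean() > 0.5:
            roots.append(node)
    if not roots:
        raise ValueError(
            "no majority-vehicle node found; inspect the embedding and "
            "vehicle annotations before computing pseudodose")
    graph.root_nodes = roots
    dist = {}
    for r in roots:
        dist[r] = nx.single_source_dijkstra_path_length(graph.graph, r,
                                                        weight="weight")
    node_psi = {n: min(dist[r].get(n, np.inf) for r in roots)
                for n in graph.graph.nodes}
    psi = np.array([node_psi[n] for n in graph.assignment])

    k = min(k_bins, len(np.unique(psi)))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(
        psi.reshape(-1, 1))
    # order bin ids by mean psi so bin 0 is the root end
    means = np.array([psi[km.labels_ == b].mean() for b in range(k)])
    order = np.argsort(means)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    bin_id = remap[km.labels_]
    bin_mean = means[order][bin_id]
    return pd.DataFrame({"psi": psi, "bin": bin_id, "psi_bin_mean": bin_mean})


class PrincipalGraphTrajectory(BaseEstimator):
    """Fit a principal-graph pseudodose on an embedding.

    ``fit(embedding, vehicle)`` learns the graph and computes pseudodose;
    fitted attributes: ``graph_``, ``pseudodose_`` (frame with psi / bin /
    psi_bin_mean).
    """

    def __init__(self, n_centroids: int = 25, k_bins: int = 10, seed: int = 0):
        self.n_centroids = n_centroids
        self.k_bins = k_bins
        self.seed = seed

    def fit(self, embedding, vehicle):
        self.graph_ = learn_principal_graph(embedding, self.n_centroids,
                                            self.seed)
        self.pseudodose_ = compute_pseudodose(self.graph_, vehicle,
                                              self.k_bins, self.seed)
        return self

    def fit_transform(self, embedding, vehicle):
        return self.fit(embedding, vehicle).pseudodose_["psi"].to_numpy()


@dataclass
class AggregateAccessibility:
    A: np.ndarray            # peaks x groups accessible-cell counts
    psi: np.ndarray          # group mean pseudodose
    S: np.ndarray            # group mean accessible-feature count per cell
    sizes: np.ndarray
    peak_names: list
    groups: list             # list of cell-index arrays


def aggregate_groups(matrix: LabeledMatrix, pseudodose: pd.DataFrame,
                     min_size: int = 50, max_size: int = 100
                     ) -> AggregateAccessibility:
    """Group cells within pseudodose bins into 50-100 cell aggregates.

    Bins with fewer than ``min_size`` cells are merged with the nearest
    adjacent bin before chunking; within each bin cells are sorted by psi
    and split into equal contiguous chunks whose sizes fall in
    [min_size, max_size] (a single remainder chunk may undershoot when the
    total does not divide evenly; it is merged into its neighbor).
    """
    n = matrix.shape[0]
    if n < min_size:
        raise ValueError(f"need >= {min_size} cells to aggregate")
    psi = pseudodose["psi"].to_numpy()
    bins = pseudodose["bin"].to_numpy()

    # merge deficient bins with their nearest adjacent bin (by bin order)
    ordered = sorted(np.unique(bins))
    members = {b: list(np.where(bins == b)[0]) for b in ordered}
    i = 0
    while i < len(ordered):
        b = ordered[i]
        if len(members[b]) < min_size and len(ordered) > 1:
            j = i + 1 if i + 1 < len(ordered) else i - 1
            members[ordered[j]].extend(members.pop(b))
            ordered.pop(i)
            i = 0  # re-scan: merges can cascade
        else:
            i += 1

    X = sp.csr_matrix(matrix.matrix)
    groups, psi_j, S_j, sizes = [], [], [], []
    for b in ordered:
        idx = np.array(members[b])
        idx = idx[np.argsort(psi[idx], kind="stable")]
        size = len(idx)
        # finest split keeping every chunk >= min_size (array_split chunk
        # sizes differ by <= 1, so they also stay <= max_size)
        n_groups = max(size // min_size, 1)
        splits = np.array_split(idx, n_groups)
        for chunk in splits:
            groups.append(chunk)
            psi_j.append(float(psi[chunk].mean()))
            sub = X[chunk]
            S_j.append(float(np.asarray(sub.sum(axis=1)).mean()))
            sizes.append(len(chunk))
    A = np.column_stack([
        np.asarray((X[g] > 0).sum(axis=0)).ravel() for g in groups])
    return AggregateAccessibility(
        A=A, psi=np.array(psi_j), S=np.array(S_j),
        sizes=np.array(sizes), peak_names=list(matrix.col_names),
        groups=groups)


def smooth_and_classify(agg: AggregateAccessibility, da_peaks,
                        spline_df: int = 3, n_bins: int = 100,
                        first_last: int = 20) -> pd.DataFrame:
    """NB-spline smoothing of aggregate accessibility; trend classification.

    ``da_peaks``: collection of peak names that are differentially
    accessible; all other peaks are classified static. Returns a frame with
    the class, argmax bin (1-based), and the 100-bin smoothed predictions.
    """
    if len(agg.psi) < spline_df * 2:
        raise ValueError("need >= 6 groups for the spline fit")
    da_peaks = set(da_peaks)
    B_psi, _ = natural_spline_basis(agg.psi, df=spline_df)
    B_S, _ = natural_spline_basis(agg.S, df=spline_df)
    X = np.column_stack([np.ones(len(agg.psi)), B_psi, B_S])
    # group sizes vary within [50, 100]; ln(size) enters as an exposure
    # offset so the smoothed score is a per-cell accessibility rate
    offset = np.log(agg.sizes.astype(float))
    # fitted rates are retrieved at the observed groups (psi_j, S_j) and
    # mapped onto 100 equally spaced pseudodose bins by interpolation, so
    # the cell-wise accessibility covariate enters at its local value
    grid = np.linspace(agg.psi.min(), agg.psi.max(), n_bins)
    order = np.argsort(agg.psi, kind="stable")

    rows = []
    for i, peak in enumerate(agg.peak_names):
        y = agg.A[i]
        fallback = False
        try:
            res = fit_negative_binomial(y, X, offset=offset)
        except Exception:
            import statsmodels.api as sm

            res = sm.GLM(y, X, family=sm.families.Poisson(),
                         offset=offset).fit()
            fallback = True
        fitted = np.exp(X @ res.params)
        pred = np.interp(grid, agg.psi[order], fitted[order])
        argmax = int(np.argmax(pred)) + 1  # 1-based bin
        if peak not in da_peaks:
            cls = "static"
        elif argmax <= first_last:
            cls = "closing"
        elif argmax > n_bins - first_last:
            cls = "opening"
        else:
            cls = "dynamic"
        rows.append(dict(peak=peak, trend_class=cls, argmax_bin=argmax,
                         poisson_fallback=fallback,
                         predictions=pred))
    return pd.DataFrame(rows).set_index("peak", drop=False).rename_axis(None)


@dataclass
class FripModelResult:
    drug: str
    lrt_stat: float
    df: int
    p: float
    full_llf: float
    reduced_llf: float
    full_params: np.ndarray
    reduced_params: np.ndarray


def fit_frip_interaction(frip, psi_binned, dose_d, drug: str = "",
                         spline_df: int = 3) -> FripModelResult:
    """Gaussian LRT for a spline(psi)*dose interaction on FRIP.

    Full model: FRIP ~ 1 + ns(psi, df) + ns(psi, df):d; reduced drops the
    interaction columns. LRT df = number of interaction terms.
    """
    frip = np.asarray(frip, dtype=float)
    d = np.asarray(dose_d, dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("dose is constant over cells: interaction inestimable")
    B, _ = natural_spline_basis(np.asarray(psi_binned, float), df=spline_df)
    X_red = np.column_stack([np.ones(len(frip)), B])
    X_full = np.column_stack([X_red, B * d[:, None]])
    stat, df, p, full, red = gaussian_lrt(frip, X_full, X_red)
    return FripModelResult(drug=drug, lrt_stat=stat, df=df, p=p,
                           full_llf=float(full.llf), reduced_llf=float(red.llf),
                           full_params=full.params, reduced_params=red.params)
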
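"""Weighted gene co-expression network construction and module analysis.

The network is built from Pearson correlations between the most variable
reporters, soft-thresholded with a power adjacency a_ij = |r_ij|^beta
where beta is the smallest integer giving an approximately scale-free
degree distribution (log-log fit R^2 above a threshold). Adjacency is
transformed to topological overlap, modules are found by average-linkage
clustering of 1 - TOM with a fixed-height branch cut, and each module is
summarised by its eigengene (first principal component).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster

# WGCNA-style palette: modules are coloured by descending size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
UNASSIGNED = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    top_fraction: float = 0.25
    beta_candidates: tuple = tuple(range(1, 21))
    scale_free_r2_min: float = 0.8
    histogram_bins: int = 10
    min_module_size: int = 20
    cut_height: float = 0.99  # absolute height on the 1 - TOM scale
    variance_statistic: str = "variance"  # or "mad"
    signed: bool = False

    def __post_init__(self):
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top fraction must lie in (0, 1]")
        if any(b < 1 for b in self.beta_candidates):
            raise ValueError("beta candidates must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("minimum module size must be >= 2")


def select_top_variable(expr: pd.DataFrame, fraction: float = 0.25,
                        statistic: str = "variance") -> pd.Index:
    """The floor(fraction * n) most variable reporters, ties by reporter id.

    ``statistic`` ranks by cross-individual variance (default) or median
    absolute deviation.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if expr.shape[0] < 1:
        raise ValueError("need at least one reporter")
    if statistic == "variance":
        spread = expr.var(axis=1, ddof=1)
    elif statistic == "mad":
        spread = (expr.sub(expr.median(axis=1), axis=0)).abs().median(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    k = int(np.floor(fraction * expr.shape[0]))
    k = max(k, 1)
    order = pd.DataFrame({"spread": spread, "gene": spread.index})
    order = order.sort_values(["spread", "gene"],
                              ascending=[False, True], kind="stable")
    return pd.Index(order["gene"].iloc[:k])


def adjacency(correlations: np.ndarray, beta: int,
              signed: bool = False) -> np.ndarray:
    """Soft-threshold power adjacency a_ij = |r_ij|^beta with zero diagonal.

    The signed variant uses ((1 + r)/2)^beta instead of the absolute
    value.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = np.asarray(correlations, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1 + r) / 2) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_r2(connectivities: np.ndarray, n_bins: int = 10
                  ) -> tuple[float, bool]:
    """Scale-free topology fit index.

    Bins connectivity k into ``n_bins`` equal-width bins on log k, then
    reports the R^2 of the least-squares line of log p(k) on the mean
    log k per bin; empty bins are skipped. Returns (R^2, degenerate
    flag); an all-equal input is flagged and scored 0.
    """
    k = np.asarray(connectivities, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.allclose(k, k[0]):
        return 0.0, True
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        xs.append(logk[sel].mean())
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, True
    res = stats.linregress(xs, ys)
    return float(res.rvalue ** 2), False


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Whole-network connectivity: row sums of the adjacency."""
    return np.asarray(adj, dtype=float).sum(axis=1)


def pick_beta(correlations: np.ndarray,
              config: NetworkConfig = NetworkConfig()) -> tuple[int, pd.DataFrame]:
    """Smallest beta whose network is approximately scale-free.

    Returns (beta, diagnostics table of R^2 per candidate). Falls back,
    with a warning, to the candidate with the highest R^2 when none
    crosses the threshold.
    """
    rows = []
    chosen = None
    for beta in config.beta_candidates:
        a = adjacency(correlations, beta, signed=config.signed)
        r2, degenerate = scale_free_r2(connectivity(a), config.histogram_bins)
        rows.append({"beta": beta, "r2": r2, "degenerate": degenerate})
        if chosen is None and r2 > config.scale_free_r2_min:
            chosen = beta
    diag = pd.DataFrame(rows)
    if chosen is None:
        chosen = int(diag.loc[diag["r2"].idxmax(), "beta"])
        warnings.warn("no candidate beta reached the scale-free fit "
                      f"threshold; using argmax-R^2 beta = {chosen}")
    return chosen, diag


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off
    the diagonal, omega_ii = 1; shared neighbours raise the overlap above
    the direct connection strength alone.
    """
    a = np.asarray(adj, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("adjacency entries must lie in [0, 1]")
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - a
    omega = (shared + a) / denom
    np.fill_diagonal(omega, 1.0)
    return omega


@dataclass
class ModulePartition:
    """Gene -> module colour assignment (``grey`` = unassigned)."""
    labels: pd.Series
    sizes: pd.Series
    cut_height: float
    join_heights: np.ndarray = field(repr=False, default=None)

    @property
    def modules(self) -> list:
        return [m for m in self.sizes.index if m != UNASSIGNED]

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def cluster_modules(tom_matrix: np.ndarray, genes,
                    config: NetworkConfig = NetworkConfig()
                    ) -> ModulePartition:
    """Average-linkage modules from topological-overlap dissimilarity.

    The dendrogram is cut at the configured absolute height on the
    1 - TOM dissimilarity scale (default 0.99: topological-overlap
    dissimilarities of unrelated genes pile up immediately below 1, so a
    fixed cut just under 1 isolates coherent branches). Branches with at
    least ``min_module_size`` members become colour-labelled modules in
    order of descending size, all other genes are grey. With all pairwise
    dissimilarities equal the result is a single module (or all grey when
    n is below the minimum size).
    """
    omega = np.asarray(tom_matrix, dtype=float)
    n = omega.shape[0]
    genes = pd.Index(genes)
    if len(genes) != n:
        raise ValueError("gene list does not match TOM size")
    if n < config.min_module_size:
        warnings.warn("fewer genes than the minimum module size: "
                      "all genes left unassigned")
        labels = pd.Series(UNASSIGNED, index=genes)
        return ModulePartition(labels=labels,
                               sizes=labels.value_counts(),
                               cut_height=np.nan, join_heights=np.array([]))
    diss = 1.0 - omega
    diss = (diss + diss.T) / 2
    np.fill_diagonal(diss, 0.0)
    condensed = diss[np.triu_indices(n, k=1)]
    linkage = average(condensed)
    heights = linkage[:, 2]
    cut = float(config.cut_height)
    branch = fcluster(linkage, t=cut, criterion="distance")
    counts = pd.Series(branch).value_counts()
    keep = counts[counts >= config.min_module_size].index
    # colour by descending size; ties broken by branch id for stability
    keep = sorted(keep, key=lambda b: (-counts[b], b))
    color_of = {b: MODULE_COLORS[i % len(MODULE_COLORS)]
                for i, b in enumerate(keep)}
    labels = pd.Series([color_of.get(b, UNASSIGNED) for b in branch],
                       index=genes)
    sizes = labels.value_counts()
    return ModulePartition(labels=labels, sizes=sizes, cut_height=cut,
                           join_heights=heights)


def module_eigengene(expr: pd.DataFrame, genes) -> pd.Series:
    """Standardized first principal component of a module's expression.

    Sign is oriented so that the eigengene correlates positively with the
    average module gene. Degenerate (zero-variance) modules return NaN.
    """
    sub = expr.loc[list(genes)].to_numpy(dtype=float)
    if sub.shape[0] < 2:
        raise ValueError("module must contain at least 2 genes")
    sd = sub.std(axis=1, ddof=1)
    if np.all(sd == 0):
        warnings.warn("degenerate module: zero variance in all genes")
        return pd.Series(np.nan, index=expr.columns)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    score = vt[0]
    mean_gene = z.mean(axis=0)
    if np.dot(score, mean_gene) < 0:
        score = -score
    score = (score - score.mean()) / score.std(ddof=1)
    return pd.Series(score, index=expr.columns)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and p) between each module eigengene and each trait."""
    rows = []
    for module in eigengenes.columns:
        for trait in traits.columns:
            pair = pd.concat([eigengenes[module], traits[trait]],
                             axis=1).dropna()
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"module": module, "trait": trait,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def set_enrichment(gene_set, module_genes, universe) -> tuple[float, float]:
    """Fold enrichment of a gene set in a module, with hypergeometric p.

    fold = (|set & module| / |module|) / (|set| / |universe|); p is the
    upper-tail hypergeometric probability of the overlap.
    """
    universe = set(universe)
    gene_set = set(gene_set) & universe
    module_genes = set(module_genes) & universe
    if not gene_set or not module_genes:
        return np.nan, 1.0
    overlap = len(gene_set & module_genes)
    m, s, N = len(module_genes), len(gene_set), len(universe)
    fold = (overlap / m) / (s / N)
    p = float(stats.hypergeom.sf(overlap - 1, N, s, m))
    return fold, p


def ko_signature(ko_expr: pd.DataFrame, wt_expr: pd.DataFrame,
                 alpha: float = 0.05) -> tuple[pd.Index, pd.DataFrame]:
    """Differentially expressed reporters between knockout and wild type.

    Per-reporter one-way ANOVA (two groups); reporters with p < alpha
    form the signature. Returns (signature index, per-reporter table).
    """
    common = ko_expr.index.intersection(wt_expr.index)
    if ko_expr.shape[1] < 2 or wt_expr.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    ko = ko_expr.loc[common].to_numpy(dtype=float)
    wt = wt_expr.loc[common].to_numpy(dtype=float)
    f, p = stats.f_oneway(ko, wt, axis=1)
    # both groups constant and equal: no evidence of change
    degenerate = np.isnan(p)
    p = np.where(degenerate, 1.0, p)
    table = pd.DataFrame({"F": f, "p": p}, index=common)
    return common[p < alpha], table
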
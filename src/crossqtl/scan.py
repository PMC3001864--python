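"""Single-QTL Haley-Knott genome scans and permutation-based FDR.

At every grid locus the trait is regressed on an intercept, the additive
genotype component L_A = P(AA) - P(BB) and the dominance component
L_D = P(AB); LOD = (n/2) log10(RSS0 / RSS1) against the intercept-only
fit. Expression traits are pre-adjusted for gender before scanning.

Two false-discovery-rate estimators are provided, matching the two ways a
permutation null is typically built: trait-by-trait nulls from many
permutations (clinical traits), and a null pooled across all reporters
from a few whole-matrix permutations (expression traits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeProbabilities, LodCurve

LOD_CAP = 300.0  # finite stand-in for a perfect fit


def adjust_for_gender(y: np.ndarray, gender: np.ndarray) -> np.ndarray:
    """Residuals of the least-squares fit y ~ 1 + gender.

    Missing values in ``y`` are preserved as NaN; the fit uses complete
    observations only. An all-one-gender input degenerates to centering.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(gender, dtype=float)
    if np.isnan(g).any():
        raise ValueError("gender covariate must not contain missing values")
    ok = ~np.isnan(y)
    if len(np.unique(g[ok])) < 2:
        warnings.warn("single-gender input: returning centered trait")
        out = y.copy()
        out[ok] = y[ok] - y[ok].mean()
        return out
    X = np.column_stack([np.ones(ok.sum()), g[ok]])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    out = y.copy()
    out[ok] = y[ok] - X @ beta
    return out


def adjust_matrix_for_gender(Y: np.ndarray, gender: np.ndarray) -> np.ndarray:
    """Column-wise gender adjustment of a (n_individuals, n_traits) matrix."""
    Y = np.asarray(Y, dtype=float)
    if np.isnan(Y).any():
        return np.column_stack([adjust_for_gender(Y[:, j], gender)
                                for j in range(Y.shape[1])])
    g = np.asarray(gender, dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def _scan_matrix(Y: np.ndarray, la: np.ndarray, ld: np.ndarray
                 ) -> tuple[np.ndarray, list]:
    """LOD matrix (n_traits, n_loci) for complete-case trait columns."""
    n, n_traits = Y.shape
    n_loci = la.shape[1]
    ybar = Y.mean(axis=0)
    rss0 = ((Y - ybar) ** 2).sum(axis=0)
    # constant traits: centering round-off leaves rss0 at ~n*eps^2*scale
    zero0 = rss0 <= (Y ** 2).sum(axis=0) * 1e-20 + 1e-300
    lod = np.empty((n_traits, n_loci))
    flags = []
    ones = np.ones(n)
    for j in range(n_loci):
        X = np.column_stack([ones, la[:, j], ld[:, j]])
        coef, res, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < 3:
            X = X[:, :2]
            coef, res, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
            flags.append(("rank_deficient", j))
        fit = X @ coef
        rss1 = ((Y - fit) ** 2).sum(axis=0)
        tiny = (rss1 <= rss0 * 1e-12) & ~zero0
        with np.errstate(divide="ignore", invalid="ignore"):
            l = 0.5 * n * np.log10(rss0 / rss1)
        l[tiny] = LOD_CAP
        l[zero0] = 0.0
        if tiny.any():
            flags.append(("lod_capped", j))
        lod[:, j] = np.clip(l, 0.0, LOD_CAP)
    return lod, flags


def _peak_coefficients(y, la_col, ld_col):
    X = np.column_stack([np.ones_like(y), la_col, ld_col])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return tuple(float(c) for c in coef)


def hk_scan(y: np.ndarray, probs: GenotypeProbabilities,
            trait: str = "trait", min_obs: int = 10) -> LodCurve:
    """Haley-Knott scan of one trait; missing observations are dropped.

    ``min_obs`` guards against uninterpretable fits on tiny samples; it
    can be lowered for toy inputs.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != probs.n_individuals:
        raise ValueError("trait vector not aligned to individuals")
    ok = ~np.isnan(y)
    if ok.sum() < max(min_obs, 4):
        raise ValueError(
            f"need at least {max(min_obs, 4)} non-missing observations")
    la, ld = probs.additive_dominance()
    lod, flags = _scan_matrix(y[ok, None], la[ok], ld[ok])
    lod = lod[0]
    peak = int(np.argmax(lod))
    coefs = _peak_coefficients(y[ok], la[ok, peak], ld[ok, peak])
    loci = probs.loci
    return LodCurve(trait=trait, loci=loci, lod=lod, peak_index=peak,
                    peak_chromosome=loci["chromosome"].iloc[peak],
                    peak_cm=float(loci["cm"].iloc[peak]),
                    peak_lod=float(lod[peak]), coefficients=coefs,
                    n_used=int(ok.sum()), flags=tuple(flags))


def hk_scan_matrix(Y: np.ndarray, probs: GenotypeProbabilities
                   ) -> np.ndarray:
    """LOD matrix (n_traits, n_loci) for a complete (n_ind, n_traits) matrix.

    Traits containing missing values fall back to per-trait scans.
    """
    Y = np.asarray(Y, dtype=float)
    la, ld = probs.additive_dominance()
    if np.isnan(Y).any():
        rows = []
        for j in range(Y.shape[1]):
            rows.append(hk_scan(Y[:, j], probs).lod)
        return np.vstack(rows)
    lod, _ = _scan_matrix(Y, la, ld)
    return lod


def scan_peaks(lod: np.ndarray, loci: pd.DataFrame) -> pd.DataFrame:
    """Peak chromosome / position / LOD per row of a LOD matrix."""
    idx = np.argmax(lod, axis=1)
    return pd.DataFrame({
        "peak_index": idx,
        "chromosome": loci["chromosome"].to_numpy()[idx],
        "peak_cm": loci["cm"].to_numpy()[idx],
        "peak_lod": lod[np.arange(lod.shape[0]), idx],
    })


@dataclass
class PermutationNull:
    """Genome-wide max LOD under permutation of individual labels."""
    max_lod: np.ndarray          # (n_perm,)
    n_perm: int
    seed: int
    full_lod: np.ndarray | None = None  # optional (n_perm, n_loci)


def permute_and_scan(y: np.ndarray, probs: GenotypeProbabilities,
                     n_perm: int, seed: int,
                     keep_full: bool = False) -> PermutationNull:
    """Permutation null for one trait.

    Individual labels of the trait are shuffled against the (intact)
    genotype rows, preserving genome-wide linkage structure; the
    genome-wide maximum LOD of each permuted scan is recorded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    yy = y[ok]
    perms = np.column_stack([yy[rng.permutation(yy.size)]
                             for _ in range(n_perm)])
    la, ld = probs.additive_dominance()
    lod, _ = _scan_matrix(perms, la[ok], ld[ok])
    return PermutationNull(max_lod=lod.max(axis=1), n_perm=n_perm, seed=seed,
                           full_lod=lod if keep_full else None)


@dataclass
class FdrTable:
    """LOD thresholds with monotone FDR estimates."""
    table: pd.DataFrame  # columns: lod, fdr (+ p for trait-wise tables)
    provenance: str
    n_perm: int

    def fdr_at(self, lod: float) -> float:
        t = self.table
        hit = t[t["lod"] <= lod]
        if hit.empty:
            return 1.0
        return float(hit["fdr"].iloc[-1])

    def threshold_for(self, fdr: float) -> float:
        t = self.table[self.table["fdr"] <= fdr]
        if t.empty:
            return np.inf
        return float(t["lod"].iloc[0])


def _tail_p(values: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Add-one permutation p-values: (1 + #{null >= v}) / (n_null + 1)."""
    null = np.sort(null)
    n = null.size
    ge = n - np.searchsorted(null, values, side="left")
    return (1.0 + ge) / (n + 1.0)


def trait_fdr(observed: pd.Series, nulls: dict) -> FdrTable:
    """Trait-wise permutation FDR for clinical-trait peak LODs.

    Each trait's peak LOD is converted to a p-value against its own
    permutation null; the same conversion is applied to the permuted peak
    LODs, and FDR at a p threshold is the average permuted discovery count
    over the observed discovery count, monotonized in the threshold.
    """
    traits = list(observed.index)
    if set(traits) != set(nulls):
        raise ValueError("trait sets of observed values and nulls differ")
    n_perm = len(next(iter(nulls.values())).max_lod)
    p_obs = np.array([_tail_p(np.array([observed[t]]),
                              nulls[t].max_lod)[0] for t in traits])
    # permuted peak p-values, per permutation replicate (n_perm, n_traits)
    p_perm = np.column_stack([_tail_p(nulls[t].max_lod, nulls[t].max_lod)
                              for t in traits])
    order = np.argsort(p_obs)
    rows = []
    for i in order:
        t = p_obs[i]
        n_disc = int((p_obs <= t).sum())
        false_disc = (p_perm <= t).sum(axis=1).mean()
        rows.append({"trait": traits[i], "lod": float(observed[traits[i]]),
                     "p": float(t),
                     "fdr": min(1.0, false_disc / max(1, n_disc))})
    table = pd.DataFrame(rows).sort_values("lod").reset_index(drop=True)
    # q-value style monotonization: FDR at a threshold is the best (lowest)
    # estimate among all thresholds at least as lenient
    table["fdr"] = np.minimum.accumulate(table["fdr"].to_numpy())
    return FdrTable(table=table, provenance="trait-wise", n_perm=n_perm)


def eqtl_fdr(observed_peaks: np.ndarray, permuted_peaks: np.ndarray,
             thresholds: np.ndarray | None = None) -> FdrTable:
    """Pooled permutation FDR for expression peak LODs.

    ``permuted_peaks`` has one row per permuted dataset (typically few),
    each holding peak LODs for every reporter; FDR(lod) is the average
    permuted exceedance count over the observed exceedance count.
    """
    observed_peaks = np.asarray(observed_peaks, dtype=float)
    permuted_peaks = np.atleast_2d(np.asarray(permuted_peaks, dtype=float))
    if thresholds is None:
        thresholds = np.unique(np.round(observed_peaks, 3))
    obs_sorted = np.sort(observed_peaks)
    perm_sorted = np.sort(permuted_peaks.ravel())
    n_sets = permuted_peaks.shape[0]
    rows = []
    for lam in thresholds:
        n_obs = observed_peaks.size - np.searchsorted(obs_sorted, lam, "left")
        n_perm_exceed = (perm_sorted.size
                         - np.searchsorted(perm_sorted, lam, "left")) / n_sets
        fdr = 1.0 if n_obs == 0 else min(1.0, n_perm_exceed / n_obs)
        rows.append({"lod": float(lam), "fdr": fdr})
    table = pd.DataFrame(rows).sort_values("lod").reset_index(drop=True)
    table["fdr"] = np.minimum.accumulate(table["fdr"].to_numpy())
    return FdrTable(table=table, provenance="pooled",
                    n_perm=n_sets)


def permute_expression_scans(Y: np.ndarray, probs: GenotypeProbabilities,
                             n_perm: int, seed: int) -> np.ndarray:
    """Peak LODs for whole-matrix permutations of an expression matrix.

    Returns (n_perm, n_reporters): each permutation shuffles individual
    labels once for the whole matrix, preserving reporter-reporter
    correlation in the null.
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    out = np.empty((n_perm, Y.shape[1]))
    for b in range(n_perm):
        idx = rng.permutation(Y.shape[0])
        lod = hk_scan_matrix(Y[idx], probs)
        out[b] = lod.max(axis=1)
    return out
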
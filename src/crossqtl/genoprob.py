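"""Genetic-map estimation and conditional genotype probabilities.

An F2 intercross segregates AA:AB:BB at 1:2:1. Conditional on the typed
markers, the genotype at any grid position is inferred with a three-state
hidden Markov model whose transition probabilities come from two
independent meioses under the Haldane (no-interference) map function.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import F2Genotypes, GeneticMap, GenotypeProbabilities

F2_PRIOR = np.array([0.25, 0.5, 0.25])


def haldane(d_cm):
    """Map distance (cM) -> recombination fraction, r = (1 - e^(-2d))/2."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def inverse_haldane(r):
    """Recombination fraction in [0, 0.5) -> map distance (cM)."""
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * rr)
    return float(d) if np.isscalar(r) else d


def transition_matrix(r: float) -> np.ndarray:
    """F2 genotype transition matrix for adjacent loci at recombination r.

    Rows/columns are AA, AB, BB; entries follow from two independent
    gametes each recombining with probability r.
    """
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


def two_locus_table(r: float) -> np.ndarray:
    """Joint P(g1, g2) for an F2 pair of loci at recombination fraction r."""
    return F2_PRIOR[:, None] * transition_matrix(r)


def _pair_loglik(r: float, counts: np.ndarray) -> float:
    table = two_locus_table(r)
    with np.errstate(divide="ignore"):
        logt = np.log(table)
    logt[np.isneginf(logt) & (counts == 0)] = 0.0
    return float((counts * logt).sum())


def estimate_pair_rf(g1: np.ndarray, g2: np.ndarray) -> float:
    """Maximum-likelihood recombination fraction for one adjacent marker pair.

    ``g1``/``g2`` are integer-coded genotypes (0/1/2, -1 missing). The
    likelihood marginalises over the unobservable phase of double
    heterozygotes through the joint two-locus genotype table, so no
    explicit phase resolution is required.
    """
    ok = (g1 >= 0) & (g2 >= 0)
    if ok.sum() == 0:
        return np.nan
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1[ok], g2[ok]), 1.0)
    if np.array_equal(g1[ok], g2[ok]):
        return 0.0
    res = minimize_scalar(lambda r: -_pair_loglik(r, counts),
                          bounds=(1e-8, 0.5 - 1e-8), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def estimate_map(genotypes: F2Genotypes) -> GeneticMap:
    """Re-estimate cM positions from the genotype data.

    Markers are kept in their given physical order per chromosome;
    adjacent-pair recombination fractions are estimated by maximum
    likelihood on the F2 two-locus table and converted to cM with the
    inverse Haldane function, then accumulated from zero.
    """
    coded = genotypes.encoded()
    marker_pos = {m: i for i, m in enumerate(genotypes.markers)}
    rows = []
    for chrom in genotypes.gmap.chromosomes:
        sub = genotypes.gmap.markers_on(chrom)
        markers = [m for m in sub.index if m in marker_pos]
        cum = 0.0
        prev_col = None
        for m in markers:
            col = coded[:, marker_pos[m]]
            if len(np.unique(col[col >= 0])) < 2:
                warnings.warn(f"monomorphic marker {m!r}: "
                              "recombination fraction undefined, skipped")
                continue
            if prev_col is not None:
                r = estimate_pair_rf(prev_col, col)
                r = min(r, 0.5 - 1e-8)
                cum += inverse_haldane(r) if np.isfinite(r) else 0.0
            rows.append((m, chrom, cum, sub.loc[m].get("mb", np.nan)))
            prev_col = col
    table = pd.DataFrame(rows, columns=["marker", "chromosome", "cm", "mb"])
    table = table.set_index("marker")
    return GeneticMap(table)


def _build_grid(sub: pd.DataFrame, step: float) -> pd.DataFrame:
    """Marker positions plus pseudomarkers every ``step`` cM."""
    cm = sub["cm"].to_numpy(dtype=float)
    lo, hi = cm.min(), cm.max()
    grid = np.arange(lo, hi + 1e-9, step) if step > 0 else np.array([])
    pseudo = [g for g in grid if np.min(np.abs(cm - g)) > 1e-6]
    rows = [{"locus": m, "cm": c, "is_marker": True,
             "mb": sub["mb"].iloc[i] if "mb" in sub.columns else np.nan}
            for i, (m, c) in enumerate(zip(sub.index, cm))]
    chrom = sub["chromosome"].iloc[0]
    rows += [{"locus": f"c{chrom}.loc{g:g}", "cm": g, "is_marker": False,
              "mb": np.nan} for g in pseudo]
    out = pd.DataFrame(rows)
    out["chromosome"] = chrom
    out = out.sort_values("cm", kind="stable").reset_index(drop=True)
    if "mb" in sub.columns and sub["mb"].notna().all() and len(sub) > 1:
        out["mb"] = np.interp(out["cm"], cm, sub["mb"].to_numpy(dtype=float))
    return out


def genotype_probabilities(genotypes: F2Genotypes,
                           gmap: GeneticMap | None = None,
                           step: float = 2.0,
                           error_rate: float = 0.001) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities on a cM grid.

    Parameters
    ----------
    step:
        Pseudomarker spacing in cM (0 disables pseudomarkers).
    error_rate:
        Genotyping error rate epsilon in [0, 0.5): the observed class is
        emitted with probability 1 - epsilon, each other class epsilon/2.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must lie in [0, 0.5)")
    gmap = gmap if gmap is not None else genotypes.gmap
    coded = genotypes.encoded()
    marker_pos = {m: i for i, m in enumerate(genotypes.markers)}
    n_ind = coded.shape[0]

    all_loci = []
    all_probs = []
    for chrom in gmap.chromosomes:
        sub = gmap.markers_on(chrom)
        sub = sub[sub["cm"].notna()]
        if sub.empty:
            continue
        grid = _build_grid(sub, step)
        n_loci = len(grid)
        # emission probabilities, (n_ind, n_loci, 3); uniform at
        # pseudomarkers and for missing genotypes
        emit = np.ones((n_ind, n_loci, 3))
        for j, row in grid.iterrows():
            if not row["is_marker"] or row["locus"] not in marker_pos:
                continue
            obs = coded[:, marker_pos[row["locus"]]]
            typed = obs >= 0
            emit[typed, j, :] = error_rate / 2.0
            emit[typed, j, obs[typed]] = 1.0 - error_rate
        # transitions between adjacent grid loci
        dists = np.diff(grid["cm"].to_numpy(dtype=float))
        trans = [transition_matrix(haldane(d)) for d in dists]

        alpha = np.empty((n_ind, n_loci, 3))
        scale = np.empty((n_ind, n_loci))
        a = F2_PRIOR[None, :] * emit[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0:1]
        for j in range(1, n_loci):
            a = (alpha[:, j - 1, :] @ trans[j - 1]) * emit[:, j, :]
            scale[:, j] = a.sum(axis=1)
            alpha[:, j, :] = a / scale[:, j:j + 1]
        beta = np.empty((n_ind, n_loci, 3))
        beta[:, -1, :] = 1.0
        for j in range(n_loci - 2, -1, -1):
            b = (beta[:, j + 1, :] * emit[:, j + 1, :]) @ trans[j].T
            beta[:, j, :] = b / b.sum(axis=1, keepdims=True)
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        all_loci.append(grid)
        all_probs.append(post)

    loci = pd.concat(all_loci, ignore_index=True)
    probs = np.concatenate(all_probs, axis=1)
    return GenotypeProbabilities(probs=probs, loci=loci,
                                 individuals=genotypes.individuals,
                                 step=step, error_rate=error_rate)
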
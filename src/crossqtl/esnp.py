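"""Matched-resampling enrichment test for an eSNP set in GWAS results.

The observed statistic is the fraction of eSNPs with association p below
a threshold (default 0.05). A null distribution is built by repeatedly
drawing random SNP sets of the same size from an eligible universe,
stratified so each draw matches the eSNP set's minor-allele-frequency and
distance-to-gene profile. By the central limit theorem the null fractions
are approximately normal, so Z = (observed - null mean) / null SD and the
enrichment p-value is the upper normal tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_THRESHOLD = 0.05
MAX_DISTANCE_BP = 1_000_000
MIN_MAF = 0.04


def eligible_universe(snps: pd.DataFrame,
                      max_distance_bp: int = MAX_DISTANCE_BP,
                      min_maf: float = MIN_MAF) -> pd.DataFrame:
    """SNPs within 1 Mb of a gene with MAF strictly above 4%.

    SNPs with missing MAF are excluded (and tallied in a warning).
    """
    maf = snps["maf"]
    n_missing = int(maf.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} SNPs with missing MAF excluded")
    keep = (snps["distance_bp"] <= max_distance_bp) & (maf > min_maf)
    return snps[keep.fillna(False)]


def observed_fraction(snp_set: pd.DataFrame,
                      threshold: float = P_THRESHOLD) -> float:
    """Fraction of the set with association p below the threshold."""
    if len(snp_set) == 0:
        raise ValueError("empty SNP set")
    return float((snp_set["p"] < threshold).mean())


def _strata(universe: pd.DataFrame, snp_set: pd.DataFrame,
            n_maf_bins: int = 10, n_distance_bins: int = 4):
    """Assign every universe SNP to a MAF-decile x distance-bin stratum.

    Bin edges come from the eSNP set's own quantiles so the null draws
    match the set's profile. Returns (universe stratum codes, set counts
    per stratum).
    """
    maf_edges = np.quantile(snp_set["maf"],
                            np.linspace(0, 1, n_maf_bins + 1))
    dist_edges = np.quantile(snp_set["distance_bp"],
                             np.linspace(0, 1, n_distance_bins + 1))
    maf_edges[0], maf_edges[-1] = -np.inf, np.inf
    dist_edges[0], dist_edges[-1] = -np.inf, np.inf
    maf_edges = np.unique(maf_edges)
    dist_edges = np.unique(dist_edges)

    def code(df):
        mi = np.clip(np.digitize(df["maf"], maf_edges) - 1,
                     0, len(maf_edges) - 2)
        di = np.clip(np.digitize(df["distance_bp"], dist_edges) - 1,
                     0, len(dist_edges) - 2)
        return mi * (len(dist_edges) - 1) + di

    u_codes = code(universe)
    s_codes = code(snp_set)
    set_counts = pd.Series(s_codes).value_counts().sort_index()
    return np.asarray(u_codes), set_counts


def sample_null_fractions(universe: pd.DataFrame, snp_set: pd.DataFrame,
                          n_resamples: int, seed: int,
                          threshold: float = P_THRESHOLD,
                          n_maf_bins: int = 10,
                          n_distance_bins: int = 4) -> np.ndarray:
    """Null sub-threshold fractions from matched random SNP sets.

    Each resample draws, without replacement and independently of other
    resamples, the same number of SNPs per MAF x distance stratum as the
    eSNP set contains. Only the count of sub-threshold SNPs per stratum
    matters for the fraction, so each stratum's contribution is drawn
    from its exact hypergeometric law — identical in distribution to
    enumerating individual SNP draws. Strata with too few universe SNPs
    borrow from the nearest stratum with spare capacity (with a warning).
    """
    if len(universe) < len(snp_set):
        raise ValueError("universe smaller than the SNP set")
    rng = np.random.default_rng(seed)
    u_codes, set_counts = _strata(universe, snp_set,
                                  n_maf_bins, n_distance_bins)
    sub = (universe["p"] < threshold).to_numpy()
    set_size = int(set_counts.sum())
    totals = {}
    hits = {}
    for code in set_counts.index:
        sel = u_codes == code
        totals[code] = int(sel.sum())
        hits[code] = int(sub[sel].sum())
    # rebalance draws that exceed a stratum's universe count
    draws = dict(set_counts)
    short = {c: draws[c] - totals[c] for c in draws if draws[c] > totals[c]}
    if short:
        warnings.warn(f"{len(short)} strata smaller than the requested "
                      "draw; borrowing from neighbouring strata")
        for c, excess in short.items():
            draws[c] = totals[c]
            for other in sorted(draws, key=lambda o: abs(o - c)):
                spare = totals.get(other, 0) - draws[other]
                if other == c or spare <= 0:
                    continue
                take = min(spare, excess)
                draws[other] += take
                excess -= take
                if excess == 0:
                    break
    counts = np.zeros(n_resamples, dtype=np.int64)
    for code, m in draws.items():
        if m == 0:
            continue
        counts += rng.hypergeometric(hits[code], totals[code] - hits[code],
                                     m, size=n_resamples)
    return counts / set_size


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n_resamples: int
    seed: int
    empirical_p: float


def z_and_p(observed: float, null_fractions: np.ndarray,
            seed: int = 0) -> EnrichmentResult:
    """Normal-tail enrichment summary against a resampled null.

    Z = (observed - null mean) / null SD; p = 1 - Phi(Z); the CI is the
    2.5/97.5 percentile band of the null fractions. The empirical
    (add-one) resampling p is reported alongside the theoretical one.
    """
    null = np.asarray(null_fractions, dtype=float)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd < 1e-12:  # fractions live in [0, 1]; this is exact-tie territory
        raise ValueError("degenerate null: zero standard deviation")
    z = (observed - mean) / sd
    p = float(stats.norm.sf(z))
    lo, hi = np.percentile(null, [2.5, 97.5])
    emp = (1.0 + (null >= observed).sum()) / (null.size + 1.0)
    return EnrichmentResult(observed=float(observed), null_mean=mean,
                            null_sd=sd, ci_low=float(lo), ci_high=float(hi),
                            z=float(z), p=p, n_resamples=null.size,
                            seed=seed, empirical_p=float(emp))


def enrichment_test(snps: pd.DataFrame, esnp_ids,
                    n_resamples: int = 100_000, seed: int = 0,
                    threshold: float = P_THRESHOLD) -> EnrichmentResult:
    """End-to-end matched-resampling test for one eSNP set."""
    universe = eligible_universe(snps)
    snp_set = universe.loc[universe.index.intersection(esnp_ids)]
    obs = observed_fraction(snp_set, threshold)
    null = sample_null_fractions(universe, snp_set, n_resamples, seed,
                                 threshold)
    return z_and_p(obs, null, seed=seed)
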
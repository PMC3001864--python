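"""eQTL catalogs, cis/trans classification, hotspot detection, replication.

An eQTL catalog holds one row per (reporter, QTL chromosome, tissue) at the
maximum LOD. An eQTL is *cis* when the QTL peak lies within +/-20 Mb of the
physical gene location on the same chromosome, *trans* otherwise. Hotspots
are genomic bins with unusually many unique reporters, judged against both
a uniform (Poisson) expectation and an empirical permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

CIS_WINDOW_MB = 20.0
MIN_POSITIVE = np.nextafter(0, 1)  # smallest positive double, ~4.9e-324


def classify_cis(qtl_chromosome, peak_mb, gene_chromosome, gene_mb,
                 window_mb: float = CIS_WINDOW_MB) -> str:
    """Classify one eQTL as ``cis`` / ``trans`` / ``unknown``.

    The +/-window boundary is inclusive; a missing gene location yields
    ``unknown`` so the record can be excluded from cis/trans tallies.
    """
    if gene_chromosome is None or gene_mb is None or (
            isinstance(gene_mb, float) and np.isnan(gene_mb)):
        return "unknown"
    if str(qtl_chromosome) != str(gene_chromosome):
        return "trans"
    return "cis" if abs(peak_mb - gene_mb) <= window_mb else "trans"


def build_catalog(peaks: pd.DataFrame, gene_locations: pd.DataFrame,
                  lod_threshold: float = 5.0, tissue: str = "tissue",
                  window_mb: float = CIS_WINDOW_MB) -> pd.DataFrame:
    """Assemble an eQTL catalog from scan peaks and gene locations.

    ``peaks`` needs columns reporter, chromosome, peak_cm, peak_lod and
    (optionally) peak_mb; ``gene_locations`` is indexed by reporter with
    columns chromosome, position_mb. Rows below the LOD threshold are
    dropped; cis/trans flags are added.
    """
    cat = peaks[peaks["peak_lod"] >= lod_threshold].copy()
    cat["tissue"] = tissue
    gl = gene_locations.reindex(cat["reporter"])
    cat["gene_chromosome"] = gl["chromosome"].to_numpy()
    cat["gene_mb"] = gl["position_mb"].to_numpy()
    cat["cis"] = [
        classify_cis(c, pm, gc, gm, window_mb)
        for c, pm, gc, gm in zip(cat["chromosome"], cat["peak_mb"],
                                 cat["gene_chromosome"], cat["gene_mb"])
    ]
    return cat.reset_index(drop=True)


def collapse_catalog(records: pd.DataFrame) -> pd.DataFrame:
    """One entry per (reporter, chromosome, tissue), keeping the max LOD."""
    if records.empty:
        return records.copy()
    idx = records.groupby(["reporter", "chromosome", "tissue"], sort=False,
                          dropna=False)["peak_lod"].idxmax()
    return records.loc[idx].reset_index(drop=True)


def tissue_sharing(catalog_a: pd.DataFrame, catalog_b: pd.DataFrame,
                   denominator: str = "union") -> dict:
    """Fraction of shared eQTL between two collapsed catalogs.

    Sharing keys are (reporter, chromosome) pairs, split by cis/trans
    status (a key counts as cis if either catalog flags it cis).
    ``denominator`` is ``union`` (default) or ``a`` (conditional on the
    first catalog).
    """
    def keyed(cat):
        return {(r, str(c)): f for r, c, f in
                zip(cat["reporter"], cat["chromosome"], cat["cis"])}

    a, b = keyed(catalog_a), keyed(catalog_b)
    out = {}
    for status in ("cis", "trans"):
        a_keys = {k for k, f in a.items() if f == status}
        b_keys = {k for k, f in b.items() if f == status}
        inter = a_keys & b_keys
        denom = a_keys | b_keys if denominator == "union" else a_keys
        if not denom:
            warnings.warn(f"empty {status} sharing denominator")
            out[status] = 0.0
        else:
            out[status] = len(inter) / len(denom)
    return out


def bin_counts(catalog: pd.DataFrame, bin_size: float = 10.0,
               unit: str = "cm") -> pd.DataFrame:
    """Unique-reporter counts per half-open genomic bin [start, start+size).

    ``unit`` selects genetic (``cm``, column peak_cm) or physical (``mb``,
    column peak_mb) binning; bins are anchored at 0 on each chromosome.
    """
    col = {"cm": "peak_cm", "mb": "peak_mb"}[unit]
    if catalog.empty:
        return pd.DataFrame(columns=["chromosome", "start", "end", "count"])
    df = catalog[["reporter", "chromosome", col]].copy()
    df["start"] = np.floor(df[col] / bin_size) * bin_size
    grouped = (df.groupby(["chromosome", "start"], sort=True)["reporter"]
               .nunique().reset_index(name="count"))
    grouped["end"] = grouped["start"] + bin_size
    return grouped[["chromosome", "start", "end", "count"]]


def genome_bin_count(loci_extent: pd.DataFrame, bin_size: float = 10.0,
                     unit: str = "cm") -> int:
    """Number of bins covering the mapped genome.

    ``loci_extent`` gives per-chromosome maximum position (column ``cm`` or
    ``mb``); every chromosome contributes ceil(extent / bin_size) bins
    (minimum one).
    """
    col = unit
    n = 0
    for _, row in loci_extent.iterrows():
        n += max(1, int(np.ceil((row[col] + 1e-9) / bin_size)))
    return n


@dataclass
class HotspotResult:
    chromosome: object
    start: float
    end: float
    unit: str
    observed: int
    expected: float
    poisson_p: float
    log10_poisson_p: float
    permutation_max: np.ndarray
    empirical_p: float


def hotspot_test(bins: pd.DataFrame, total_eqtl: int, n_bins: int,
                 permuted_catalogs: list, bin_size: float = 10.0,
                 unit: str = "cm") -> list:
    """Score every occupied bin against Poisson and permutation nulls.

    The uniform expectation per bin is total_eqtl / n_bins; the Poisson
    upper tail P(X >= observed) is evaluated in log space and floored at
    the smallest positive double. The empirical p compares the observed
    count with the genome-wide *maximum* bin count of each permuted
    catalog: (1 + #{perm max >= obs}) / (n_perm + 1).
    """
    if n_bins <= 0:
        raise ValueError("number of genome bins must be positive")
    expected = total_eqtl / n_bins
    perm_max = np.array([
        0 if pc.empty else
        bin_counts(pc, bin_size=bin_size, unit=unit)["count"].max()
        for pc in permuted_catalogs
    ])
    n_perm = len(perm_max)
    results = []
    for _, row in bins.iterrows():
        obs = int(row["count"])
        if obs == 0:
            logp = 0.0
        else:
            logp = stats.poisson.logsf(obs - 1, expected)
            if not np.isfinite(logp):
                # scipy's sf underflows for extreme counts; sum the tail
                # pmf in log space instead
                ks = np.arange(obs, obs + max(1000, int(10 * expected) + 1))
                logp = float(special.logsumexp(
                    stats.poisson.logpmf(ks, expected)))
        p = float(np.exp(logp))
        p = max(p, MIN_POSITIVE) if obs > 0 else 1.0
        emp = (1.0 + (perm_max >= obs).sum()) / (n_perm + 1.0) \
            if n_perm else np.nan
        results.append(HotspotResult(
            chromosome=row["chromosome"], start=float(row["start"]),
            end=float(row["end"]), unit=unit, observed=obs,
            expected=expected, poisson_p=p,
            log10_poisson_p=float(logp / np.log(10)),
            permutation_max=perm_max, empirical_p=emp))
    return results


@dataclass
class ReplicationSummary:
    n_tested: int
    n_replicated: int
    n_missing: int
    rule: str
    fraction: float


def replication_analysis(signature_reporters, cohort_lod: pd.DataFrame,
                         loci: pd.DataFrame, chromosome,
                         rule: str = "lod2_anywhere",
                         interval_cm: tuple = (30.0, 40.0)
                         ) -> ReplicationSummary:
    """Replication of a hotspot signature in a second cohort.

    ``cohort_lod`` is a reporter x locus LOD matrix on the second cohort's
    grid (``loci``). Rule ``lod2_anywhere`` counts a reporter as
    replicated when its max LOD on the stated chromosome is >= 2; rule
    ``lod3_interval`` requires LOD >= 3 with the chromosome-wide max-LOD
    position inside ``interval_cm``.
    """
    on = (loci["chromosome"].astype(str) == str(chromosome)).to_numpy()
    if not on.any():
        raise ValueError(f"no loci on chromosome {chromosome!r}")
    cm = loci["cm"].to_numpy()[on]
    present = [r for r in signature_reporters if r in cohort_lod.index]
    n_missing = len(list(signature_reporters)) - len(present)
    sub = cohort_lod.loc[present].to_numpy()[:, on]
    if rule == "lod2_anywhere":
        ok = sub.max(axis=1) >= 2.0
    elif rule == "lod3_interval":
        peak_pos = cm[np.argmax(sub, axis=1)]
        ok = (sub.max(axis=1) >= 3.0) & (peak_pos >= interval_cm[0]) \
            & (peak_pos <= interval_cm[1])
    else:
        raise ValueError(f"unknown replication rule {rule!r}")
    n_rep = int(ok.sum())
    frac = n_rep / len(present) if present else np.nan
    return ReplicationSummary(n_tested=len(present), n_replicated=n_rep,
                              n_missing=n_missing, rule=rule, fraction=frac)


def signature_pc1(expr: pd.DataFrame, signature_reporters) -> pd.Series:
    """First principal component of the standardized signature submatrix.

    The score's sign is oriented so the sum of reporter loadings is
    positive. Returns one score per individual.
    """
    reporters = [r for r in signature_reporters if r in expr.index]
    if len(reporters) < 2:
        raise ValueError("need at least 2 signature reporters")
    sub = expr.loc[reporters].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # rows are reporters, columns individuals; PC1 over individuals
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    score = vt[0] * s[0]
    if u[:, 0].sum() < 0:
        score = -score
    return pd.Series(score, index=expr.columns, name="pc1")


def correlate_pc_traits(score: pd.Series, traits: pd.DataFrame
                        ) -> pd.DataFrame:
    """Pearson correlation of a per-individual score with each trait.

    Pairwise-complete observations; two-sided p from the t approximation.
    Traits with fewer than 3 complete pairs report NA with a flag.
    """
    rows = []
    for name in traits.columns:
        pair = pd.concat([score, traits[name]], axis=1, join="inner").dropna()
        if len(pair) < 3:
            rows.append({"trait": name, "r": np.nan, "p": np.nan,
                         "n": len(pair), "flag": "too_few_pairs"})
            continue
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"trait": name, "r": float(r), "p": float(p),
                     "n": len(pair), "flag": ""})
    return pd.DataFrame(rows)
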
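"""Likelihood-based causality model selection for locus-transcript-trait
triplets, plus causal-gene enrichment statistics.

Given a locus L shared by a transcript R and a clinical trait C, three
generative models are compared:

* M1 (causal):      L -> R -> C, likelihood P(R|L) P(C|R)
* M2 (reactive):    L -> C -> R, likelihood P(C|L) P(R|C)
* M3 (independent): L -> R and L -> C, likelihood P(R|L) P(C|L)

The genotype-conditional terms are three-component normal mixtures over
the genotype posterior at L (one mean per genotype class, common
variance); the trait-conditional terms are simple linear regressions with
normal errors. The common P(L) factor cancels between models and is
omitted. Each model's likelihood is maximised and the smallest AIC wins;
ties and degenerate fits yield ``no_call``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneticMap, LodCurve

AIC_TIE_TOL = 1e-9
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# component fits

def _mixture_loglik(x: np.ndarray, w: np.ndarray, mu: np.ndarray,
                    var: float) -> float:
    dens = np.exp(-0.5 * (x[:, None] - mu[None, :]) ** 2 / var) \
        / np.sqrt(2 * np.pi * var)
    mix = (w * dens).sum(axis=1)
    mix = np.maximum(mix, 1e-300)
    return float(np.log(mix).sum())


def fit_genotype_normal(x: np.ndarray, w: np.ndarray,
                        tol: float = 1e-8, max_iter: int = 500
                        ) -> tuple[float, np.ndarray, float]:
    """Maximise the genotype-mixture normal likelihood P(x | L).

    ``w`` holds the 3-class genotype posterior at L per individual; the
    model has one mean per genotype class and a common variance. With hard
    (one-hot) weights the EM converges in a single step to the group
    means; with soft weights the posterior weights are refined.
    Returns (max log-likelihood, means, variance).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    totals = w.sum(axis=0)
    mu = np.where(totals > 0, (w * x[:, None]).sum(axis=0)
                  / np.maximum(totals, 1e-12), x.mean())
    var = float(((w * (x[:, None] - mu[None, :]) ** 2).sum()) / x.size)
    if var <= 1e-12:
        return -np.inf, mu, 0.0
    ll = _mixture_loglik(x, w, mu, var)
    for _ in range(max_iter):
        dens = np.exp(-0.5 * (x[:, None] - mu[None, :]) ** 2 / var) \
            / np.sqrt(2 * np.pi * var)
        resp = w * dens
        resp_sum = resp.sum(axis=1, keepdims=True)
        resp = resp / np.maximum(resp_sum, 1e-300)
        totals = resp.sum(axis=0)
        mu = np.where(totals > 0, (resp * x[:, None]).sum(axis=0)
                      / np.maximum(totals, 1e-12), mu)
        var = float((resp * (x[:, None] - mu[None, :]) ** 2).sum() / x.size)
        if var <= 1e-12:
            return -np.inf, mu, 0.0
        new_ll = _mixture_loglik(x, w, mu, var)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            break
        ll = new_ll
    return ll, mu, var


def fit_linear_normal(y: np.ndarray, x: np.ndarray) -> float:
    """Max log-likelihood of y ~ a + b x with normal errors (MLE variance)."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    var = float((resid ** 2).mean())
    if var <= 1e-12:
        return -np.inf
    return -0.5 * n * (_LOG2PI + np.log(var) + 1.0)


# ---------------------------------------------------------------------------
# the model-selection test

@dataclass
class CausalityCall:
    verdict: str  # causal | reactive | independent | no_call
    aic: dict = field(default_factory=dict)
    loglik: dict = field(default_factory=dict)
    k: dict = field(default_factory=dict)
    reason: str = ""


def lcms(probs_at_locus: np.ndarray, R: np.ndarray, C: np.ndarray,
         hard_calls: bool = False, min_n: int = 30) -> CausalityCall:
    """Run the three-model AIC test at one locus.

    Parameters
    ----------
    probs_at_locus:
        (n, 3) genotype posterior at the test marker L.
    R, C:
        Transcript and trait vectors aligned to the same individuals;
        rows with any missing value are dropped.
    hard_calls:
        Replace the posterior with a one-hot vector on its argmax.
    """
    w = np.asarray(probs_at_locus, dtype=float)
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    ok = ~(np.isnan(R) | np.isnan(C) | np.isnan(w).any(axis=1))
    w, R, C = w[ok], R[ok], C[ok]
    if R.size < min_n:
        return CausalityCall("no_call", reason="too_few_complete_triplets")
    if np.var(R) <= 1e-12 or np.var(C) <= 1e-12:
        return CausalityCall("no_call", reason="constant_input")
    if hard_calls:
        hard = np.zeros_like(w)
        hard[np.arange(w.shape[0]), np.argmax(w, axis=1)] = 1.0
        w = hard

    ll_R_L, _, _ = fit_genotype_normal(R, w)
    ll_C_L, _, _ = fit_genotype_normal(C, w)
    ll_C_R = fit_linear_normal(C, R)
    ll_R_C = fit_linear_normal(R, C)
    loglik = {"causal": ll_R_L + ll_C_R,
              "reactive": ll_C_L + ll_R_C,
              "independent": ll_R_L + ll_C_L}
    k = {"causal": 7, "reactive": 7, "independent": 8}
    if not all(np.isfinite(v) for v in loglik.values()):
        return CausalityCall("no_call", loglik=loglik, k=k,
                             reason="degenerate_fit")
    aic = {m: 2 * k[m] - 2 * loglik[m] for m in loglik}
    ordered = sorted(aic, key=aic.get)
    best, second = ordered[0], ordered[1]
    if aic[second] - aic[best] < AIC_TIE_TOL:
        return CausalityCall("no_call", aic=aic, loglik=loglik, k=k,
                             reason="aic_tie")
    return CausalityCall(best, aic=aic, loglik=loglik, k=k)


# ---------------------------------------------------------------------------
# cQTL:eQTL overlap detection

@dataclass
class OverlapPair:
    trait: str
    reporter: str
    chromosome: object
    trait_peak_cm: float
    expression_peak_cm: float
    marker: str
    marker_cm: float


def _chromosome_peaks(curve: LodCurve, peak_lod: float,
                      overlap_lod: float) -> list:
    """Per-chromosome peaks with their LOD > overlap_lod support runs."""
    out = []
    loci = curve.loci
    for chrom in dict.fromkeys(loci["chromosome"]):
        mask = (loci["chromosome"] == chrom).to_numpy()
        lod = curve.lod[mask]
        cm = loci["cm"].to_numpy()[mask]
        i = int(np.argmax(lod))
        if lod[i] < peak_lod:
            continue
        above = lod > overlap_lod
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < len(lod) - 1 and above[hi + 1]:
            hi += 1
        out.append((chrom, float(cm[i]), float(cm[lo]), float(cm[hi])))
    return out


def find_overlaps(trait_curves: list, expression_curves: list,
                  gmap: GeneticMap, peak_lod: float = 2.0,
                  overlap_lod: float = 1.0) -> list:
    """Collect cQTL:eQTL overlaps and pick the test marker L for each.

    A pair is recorded when a trait peak and an expression peak on the
    same chromosome (both with LOD >= ``peak_lod``) have intersecting
    LOD > ``overlap_lod`` support regions. L is the genotyped marker
    nearest the midpoint of the two peak positions (ties to the lower cM).
    """
    import warnings as _warnings
    expr_peaks = {}
    for ec in expression_curves:
        expr_peaks[ec.trait] = _chromosome_peaks(ec, peak_lod, overlap_lod)
    pairs = []
    for tc in trait_curves:
        for chrom, t_cm, t_lo, t_hi in _chromosome_peaks(
                tc, peak_lod, overlap_lod):
            markers = gmap.markers_on(chrom)
            for reporter, peaks in expr_peaks.items():
                for e_chrom, e_cm, e_lo, e_hi in peaks:
                    if e_chrom != chrom:
                        continue
                    if e_lo > t_hi or t_lo > e_hi:
                        continue
                    if markers.empty:
                        _warnings.warn(
                            f"no genotyped marker on chromosome {chrom!r}; "
                            "overlap dropped")
                        continue
                    mid = 0.5 * (t_cm + e_cm)
                    cm_arr = markers["cm"].to_numpy(dtype=float)
                    dist = np.abs(cm_arr - mid)
                    # tie -> lower cM: stable argmin over ascending cM
                    j = int(np.argmin(dist))
                    pairs.append(OverlapPair(
                        trait=tc.trait, reporter=reporter, chromosome=chrom,
                        trait_peak_cm=t_cm, expression_peak_cm=e_cm,
                        marker=markers.index[j],
                        marker_cm=float(cm_arr[j])))
    return pairs


# ---------------------------------------------------------------------------
# enrichment summaries

def causal_enrichment(n_causal_signature: int, signature_size: int,
                      n_causal_array: int, array_size: int
                      ) -> tuple[float, float]:
    """Fold enrichment of causal reporters in a signature, with Fisher p.

    fold = (causal-in-signature / signature size)
         / (causal-on-array / array size);
    p is the one-sided (greater) Fisher exact probability on the 2x2
    table of signature membership x causal status.
    """
    if not (0 <= n_causal_signature <= signature_size <= array_size):
        raise ValueError("inconsistent nested counts")
    if not (n_causal_signature <= n_causal_array <= array_size):
        raise ValueError("inconsistent nested counts")
    if n_causal_array == 0 or signature_size == 0:
        return np.nan, 1.0
    fold = (n_causal_signature / signature_size) \
        / (n_causal_array / array_size)
    table = [[n_causal_signature, signature_size - n_causal_signature],
             [n_causal_array - n_causal_signature,
              array_size - signature_size - n_causal_array
              + n_causal_signature]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(fold), float(p)


def coverage_fraction(n_in_signature: int, n_total_causal: int) -> float:
    """Percent of all causal reporters captured by the signature."""
    if not 0 <= n_in_signature <= max(n_total_causal, 0):
        raise ValueError("count exceeds total")
    if n_total_causal == 0:
        return np.nan
    return 100.0 * n_in_signature / n_total_causal


# ---------------------------------------------------------------------------
# calibration harness

def simulate_triplet(model: str, n: int, rng: np.random.Generator,
                     effect: float = 1.0, noise_sd: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one (genotype posterior, R, C) triplet under a generative model.

    Genotypes follow the 1:2:1 F2 law and are observed without error
    (one-hot posteriors). Under ``causal``: R = effect * dosage + e1,
    C = R + e2; ``reactive`` is the mirror image; ``independent`` drives
    R and C from the genotype with independent noises.
    """
    g = rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
    w = np.eye(3)[g]
    dosage = 1.0 - g
    e1 = rng.normal(0, noise_sd, n)
    e2 = rng.normal(0, noise_sd, n)
    if model == "causal":
        R = effect * dosage + e1
        C = R + e2
    elif model == "reactive":
        C = effect * dosage + e1
        R = C + e2
    elif model == "independent":
        R = effect * dosage + e1
        C = effect * dosage + e2
    else:
        raise ValueError(f"unknown model {model!r}")
    return w, R, C


def calibration_table(n_reps: int = 500, n: int = 300, effect: float = 1.0,
                      noise_sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Verdict rates of the AIC test under each generative model.

    Returns a model x verdict table of call fractions across ``n_reps``
    simulated triplets per model.
    """
    rng = np.random.default_rng(seed)
    verdicts = ["causal", "reactive", "independent", "no_call"]
    rows = {}
    for model in ("causal", "reactive", "independent"):
        counts = dict.fromkeys(verdicts, 0)
        for _ in range(n_reps):
            w, R, C = simulate_triplet(model, n, rng, effect, noise_sd)
            counts[lcms(w, R, C).verdict] += 1
        rows[model] = {v: counts[v] / n_reps for v in verdicts}
    return pd.DataFrame(rows).T
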
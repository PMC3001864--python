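"""Core data containers shared across the pipeline.

Conventions
-----------
* Genotypes are coded ``AA``/``AB``/``BB`` with ``NA`` for missing; the
  integer encoding is 0/1/2 with -1 for missing.
* Genetic positions are centimorgans (floating point); physical positions
  are megabases (Mb) or base pairs (1-based) depending on the table.
* Expression matrices are reporter x individual (log-ratio scale).
* Trait tables are individual x trait, with gender carried separately as a
  0/1 series (0 = female, 1 = male).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_CODES = ("AA", "AB", "BB")

_CODE_TO_INT = {"AA": 0, "AB": 1, "BB": 2, "A": 0, "H": 1, "B": 2,
                "0": 0, "1": 1, "2": 2}
_MISSING_TOKENS = {"NA", "", "-", "NaN", "nan", None}


def encode_genotypes(geno: pd.DataFrame) -> np.ndarray:
    """Map a string-coded genotype table to an int8 array (missing -> -1)."""
    out = np.full(geno.shape, -1, dtype=np.int8)
    values = geno.to_numpy()
    for code, i in _CODE_TO_INT.items():
        out[values == code] = i
    # numeric tables (already 0/1/2) pass through
    if np.issubdtype(values.dtype, np.number):
        numeric = values.astype(float)
        ok = np.isfinite(numeric)
        out[ok] = numeric[ok].astype(np.int8)
    return out


def decode_genotypes(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_genotypes` (missing -> ``NA``)."""
    lookup = np.array(["NA", "AA", "AB", "BB"], dtype=object)
    return lookup[np.asarray(codes, dtype=int) + 1]


@dataclass
class GeneticMap:
    """Ordered marker map: one row per marker with chromosome / cM / Mb.

    Markers must appear in non-decreasing cM order within each chromosome
    and have unique identifiers.
    """

    table: pd.DataFrame  # index: marker id; columns: chromosome, cm, mb

    def __post_init__(self) -> None:
        required = {"chromosome", "cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            if not sub["cm"].is_monotonic_increasing:
                raise ValueError(
                    f"marker positions not sorted on chromosome {chrom!r}")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    def markers_on(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    def interpolate_mb(self, chrom, cm: float) -> float:
        """Physical position at a cM location, linear between flanking markers."""
        sub = self.markers_on(chrom)
        if "mb" not in sub.columns or sub["mb"].isna().all():
            raise ValueError(f"no Mb coordinates for chromosome {chrom!r}")
        return float(np.interp(cm, sub["cm"].to_numpy(), sub["mb"].to_numpy()))


@dataclass
class F2Genotypes:
    """Individuals x markers F2 genotype matrix plus its genetic map."""

    genotypes: pd.DataFrame  # individuals x markers, codes AA/AB/BB, NaN missing
    gmap: GeneticMap
    gender: pd.Series | None = None  # 0 = female, 1 = male

    def __post_init__(self) -> None:
        if self.genotypes.index.duplicated().any():
            dup = self.genotypes.index[self.genotypes.index.duplicated()][0]
            raise ValueError(f"duplicate individual id: {dup!r}")
        unknown = [m for m in self.genotypes.columns
                   if m not in self.gmap.table.index]
        if unknown:
            raise ValueError(f"markers absent from map: {unknown[:5]}")

    @property
    def individuals(self) -> pd.Index:
        return self.genotypes.index

    @property
    def markers(self) -> pd.Index:
        return self.genotypes.columns

    def encoded(self) -> np.ndarray:
        return encode_genotypes(self.genotypes)


@dataclass
class GenotypeProbabilities:
    """Conditional genotype probabilities on a cM grid.

    ``probs`` has shape (n_individuals, n_loci, 3) holding P(AA), P(AB),
    P(BB); each triple sums to one. ``loci`` has one row per grid locus with
    chromosome, cm, optional mb, locus name, and a pseudomarker flag.
    """

    probs: np.ndarray
    loci: pd.DataFrame  # columns: chromosome, cm, mb (opt), locus, is_marker
    individuals: pd.Index
    step: float
    error_rate: float

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.probs.shape[1]

    def additive_dominance(self) -> tuple[np.ndarray, np.ndarray]:
        """Haley-Knott regressors: additive P(AA)-P(BB) and dominance P(AB)."""
        la = self.probs[:, :, 0] - self.probs[:, :, 2]
        ld = self.probs[:, :, 1]
        return la, ld

    def at_locus(self, index: int) -> np.ndarray:
        return self.probs[:, index, :]

    def nearest_locus(self, chrom, cm: float) -> int:
        on = np.flatnonzero((self.loci["chromosome"] == chrom).to_numpy())
        if on.size == 0:
            raise KeyError(f"no loci on chromosome {chrom!r}")
        return int(on[np.argmin(np.abs(self.loci["cm"].to_numpy()[on] - cm))])


@dataclass
class LodCurve:
    """Single-trait genome scan result."""

    trait: str
    loci: pd.DataFrame
    lod: np.ndarray
    peak_index: int
    peak_chromosome: object
    peak_cm: float
    peak_lod: float
    coefficients: tuple  # (mu, additive, dominance) at the peak
    n_used: int
    flags: tuple = field(default_factory=tuple)

    def on_chromosome(self, chrom) -> np.ndarray:
        mask = (self.loci["chromosome"] == chrom).to_numpy()
        return self.lod[mask]
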
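"""Readers and writers for the pipeline's table dialects.

All on-disk tables are UTF-8 TSV (CSV accepted on read) with ``NA`` as
the missing token. Genotype tables accept ``AA/AB/BB``, ``A/H/B`` or
``0/1/2`` codes and either orientation (individuals x markers or the
transpose); base-pair coordinates are 1-based, cM positions floating
point.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import F2Genotypes, GeneticMap

VALID_GENO_CODES = {"AA", "AB", "BB", "A", "H", "B", "0", "1", "2"}
_NA = {"NA", "", "-", "nan", "NaN"}


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, index_col=0) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=_sep_for(path), index_col=index_col,
                           dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# genetic map

def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.lower() for c in df.columns]
    df = df.rename(columns={"chr": "chromosome", "position_cm": "cm",
                            "position_mb": "mb"})
    df["chromosome"] = df["chromosome"].astype(str)
    return GeneticMap(df.set_index("marker"))


def write_map(gmap: GeneticMap, path) -> None:
    out = gmap.table.reset_index()
    cols = ["marker", "chromosome", "cm"] + (
        ["mb"] if "mb" in out.columns else [])
    out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# genotypes

def _normalise_genotypes(raw: pd.DataFrame, path) -> pd.DataFrame:
    values = raw.to_numpy(dtype=object)
    out = np.full(raw.shape, np.nan, dtype=object)
    mapping = {"A": "AA", "H": "AB", "B": "BB", "AA": "AA", "AB": "AB",
               "BB": "BB", "0": "AA", "1": "AB", "2": "BB"}
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(values[i, j]).strip()
            if tok in _NA:
                continue
            if tok not in mapping:
                raise ValueError(
                    f"unknown genotype code {tok!r} at row "
                    f"{raw.index[i]!r}, column {raw.columns[j]!r} in {path}")
            out[i, j] = mapping[tok]
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def read_genotypes(path, gmap: GeneticMap,
                   orientation: str = "auto") -> F2Genotypes:
    """Read a genotype table and validate it against the map.

    ``orientation`` is ``individuals`` (rows are individuals),
    ``markers`` (rows are markers) or ``auto`` (detected from the map:
    unambiguous only when exactly one axis matches marker ids).
    """
    raw = _read_table(path)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate id {dup!r} in {path}")
    known = set(gmap.table.index)
    rows_are_markers = len(set(raw.index) & known) > len(
        set(raw.columns) & known)
    if orientation == "auto":
        cols_match = len(set(raw.columns) & known)
        rows_match = len(set(raw.index) & known)
        if cols_match == rows_match:
            raise ValueError("genotype orientation ambiguous; pass "
                             "orientation='individuals' or 'markers'")
        if rows_are_markers:
            raw = raw.T
    elif orientation == "markers":
        raw = raw.T
    elif orientation != "individuals":
        raise ValueError(f"unknown orientation {orientation!r}")
    geno = _normalise_genotypes(raw, path)
    return F2Genotypes(genotypes=geno, gmap=gmap)


def write_genotypes(genotypes: F2Genotypes, path) -> None:
    genotypes.genotypes.rename_axis("id").to_csv(
        path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# numeric matrices and tables

def _read_numeric(path, what: str) -> pd.DataFrame:
    df = _read_table(path)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        for i, tok in enumerate(df[col]):
            tok = str(tok).strip()
            if tok in _NA:
                continue
            try:
                out.iloc[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"non-numeric {what} value {tok!r} at row "
                    f"{df.index[i]!r}, column {col!r} in {path}") from None
    return out


def read_expression(path) -> pd.DataFrame:
    """Reporter x individual expression matrix (log-ratio scale)."""
    return _read_numeric(path, "expression")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("reporter").to_csv(path, sep="\t", na_rep="NA",
                                        float_format="%.6g")


def read_traits(path) -> pd.DataFrame:
    """Individual x trait table; a ``gender`` column is allowed."""
    return _read_numeric(path, "trait")


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.rename_axis("id").to_csv(path, sep="\t", na_rep="NA",
                                    float_format="%.6g")


def read_snps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     na_values=sorted(_NA), keep_default_na=False)
    return df


def write_snps(snps: pd.DataFrame, path) -> None:
    snps.rename_axis("snp").to_csv(path, sep="\t", na_rep="NA")


def align_individuals(*tables: pd.Index, min_overlap: float = 0.5
                      ) -> tuple[pd.Index, dict]:
    """Intersect individual ids across tables with an explicit report.

    Raises when the intersection covers less than ``min_overlap`` of any
    table (almost certainly misaligned inputs).
    """
    common = tables[0]
    for t in tables[1:]:
        common = common.intersection(t)
    report = {f"table_{i}": {"n": len(t), "n_shared": len(common),
                             "fraction": len(common) / max(1, len(t))}
              for i, t in enumerate(tables)}
    for name, info in report.items():
        if info["fraction"] < min_overlap:
            raise ValueError(
                f"only {info['n_shared']}/{info['n']} individuals of "
                f"{name} match the other tables; inputs look misaligned")
    return common, report


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Pipeline thresholds and permutation counts."""
    cis_window_mb: float = 20.0
    eqtl_lod: float = 5.0
    cqtl_lod: float = 4.3
    suggestive_lod: float = 3.0
    hotspot_bin_cm: float = 10.0
    hotspot_bin_mb: float = 10.0
    replication_interval_cm: tuple = (30.0, 40.0)
    n_perm_cqtl: int = 1000
    n_perm_eqtl: int = 5
    grid_step_cm: float = 2.0
    genotype_error_rate: float = 0.001
    network: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name in ("cis_window_mb", "eqtl_lod", "cqtl_lod",
                     "suggestive_lod", "hotspot_bin_cm", "hotspot_bin_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["replication_interval_cm"] = list(d["replication_interval_cm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "replication_interval_cm" in d:
            d["replication_interval_cm"] = tuple(d["replication_interval_cm"])
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, stage: str, config: RunConfig,
                   extra: dict | None = None) -> Path:
    from . import __version__
    manifest = {"stage": stage, "version": __version__,
                "seed": config.seed, "config_hash": config_hash(config),
                "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
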
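"""Synthetic F2 intercross generator with known ground truth.

Emulates the statistical structure of a two-strain mouse intercross
expression-genetics study: 1:2:1 genotype segregation under a Haldane
(no-interference) map, a chromosome-localised trans-eQTL hotspot driving a
block of transcripts, cis eQTL at the genes' own locations, gender effects,
clinical traits that are causal-downstream / reactive-upstream /
independent relative to the hotspot transcripts, and a GWAS SNP universe
containing an enriched eSNP subset.

Every generator takes an explicit seed through :class:`SimulationConfig`
and is byte-reproducible for a fixed (config, seed) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import F2Genotypes, GeneticMap, decode_genotypes
from .genoprob import haldane

# Approximate autosomal genetic lengths (cM) of a mouse map.
DEFAULT_CHROMOSOME_LENGTHS = (
    98, 103, 82, 88, 90, 79, 89, 76, 75, 77,
    88, 64, 67, 66, 59, 57, 61, 59, 57,
)


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_cm: float
    mb_per_cm: float = 2.0
    marker_cm: tuple | None = None  # explicit marker positions (optional)


@dataclass(frozen=True)
class HotspotSpec:
    """A trans-eQTL hotspot: one locus driving many distal transcripts."""
    chromosome: str = "8"
    position_cm: float = 35.0
    n_trans_genes: int = 200
    effect: float = 1.0       # additive effect in residual-SD units
    sign_mix: float = 0.25    # fraction of driven genes with negative effect


@dataclass(frozen=True)
class TraitSpec:
    """A clinical trait and its causal architecture at the hotspot locus.

    ``architecture`` is one of ``causal`` (locus -> transcripts -> trait),
    ``reactive`` (locus -> trait -> transcripts) or ``independent``
    (locus -> transcripts and locus -> trait with independent noises).
    """
    name: str
    architecture: str
    link_coefficient: float = 1.0
    noise_sd: float = 1.0
    locus_effect: float = 1.0  # used by reactive / independent architectures
    n_linked: int = 20         # reporters re-generated downstream (reactive)


@dataclass(frozen=True)
class SnpSpec:
    n_snps: int = 20000
    maf_range: tuple = (0.01, 0.5)
    esnp_fraction: float = 0.1
    pi_enriched: float = 0.10   # P(association p < 0.05) within the eSNP set
    distance_scale_bp: float = 300_000.0


@dataclass(frozen=True)
class SimulationConfig:
    n_f2: int = 360
    chromosomes: tuple = tuple(
        ChromosomeSpec(str(i + 1), float(l))
        for i, l in enumerate(DEFAULT_CHROMOSOME_LENGTHS))
    marker_spacing_cm: float = 5.0
    missing_rate: float = 0.02
    hotspot: HotspotSpec = HotspotSpec()
    n_cis_genes: int = 100
    cis_effect: float = 1.5
    n_null_genes: int = 1700
    gender_effect_sd: float = 0.3
    residual_sd: float = 1.0
    trait_specs: tuple = (
        TraitSpec("fat_mass", "causal", 1.0, 1.0),
        TraitSpec("weight", "reactive", 1.0, 1.0),
        TraitSpec("glucose", "independent", 1.0, 1.0),
    )
    snp_spec: SnpSpec = SnpSpec()
    seed: int = 0

    def __post_init__(self):
        if self.n_f2 <= 0:
            raise ValueError("n_f2 must be positive")
        if not self.chromosomes:
            raise ValueError("chromosome list must be non-empty")
        if self.marker_spacing_cm <= 0:
            raise ValueError("marker spacing must be positive")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing rate must lie in [0, 1]")
        if not 0 <= self.hotspot.sign_mix <= 1:
            raise ValueError("hotspot sign mix must lie in [0, 1]")
        for spec in self.trait_specs:
            if spec.architecture not in {"causal", "reactive", "independent"}:
                raise ValueError(
                    f"unknown trait architecture {spec.architecture!r}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class TruthTable:
    """Ground truth for a simulated study; one record per simulated signal."""
    genes: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    snps: pd.DataFrame | None = None

    def merge(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            genes=other.genes if other.genes is not None else self.genes,
            traits=other.traits if other.traits is not None else self.traits,
            snps=other.snps if other.snps is not None else self.snps,
        )


def _marker_grid(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom in config.chromosomes:
        if chrom.marker_cm is not None:
            positions = np.asarray(chrom.marker_cm, dtype=float)
        else:
            positions = np.arange(0.0, chrom.length_cm + 1e-9,
                                  config.marker_spacing_cm)
        for j, cm in enumerate(positions):
            rows.append({
                "marker": f"D{chrom.name}M{j + 1}",
                "chromosome": chrom.name,
                "cm": float(cm),
                "mb": float(cm * chrom.mb_per_cm),
            })
    return pd.DataFrame(rows).set_index("marker")


def simulate_f2(config: SimulationConfig) -> tuple[F2Genotypes, TruthTable]:
    """Simulate F2 genotypes marker-by-marker under the Haldane model.

    Each individual carries two independent gametes. A gamete's allele
    chain is Markov along the chromosome: the allele at the first marker is
    Bernoulli(1/2) and switches between adjacent markers with probability
    equal to the Haldane recombination fraction for the interval — exactly
    the marker-restricted law of a Poisson crossover process with uniform
    crossover positions and no interference.
    """
    rng = np.random.default_rng(config.seed)
    gmap_table = _marker_grid(config)
    n = config.n_f2
    columns = {}
    for chrom in config.chromosomes:
        sub = gmap_table[gmap_table["chromosome"] == chrom.name]
        cm = sub["cm"].to_numpy()
        rfs = haldane(np.diff(cm))
        gametes = np.empty((2, n, len(cm)), dtype=np.int8)
        gametes[:, :, 0] = rng.random((2, n)) < 0.5
        for j, r in enumerate(rfs):
            flip = rng.random((2, n)) < r
            gametes[:, :, j + 1] = gametes[:, :, j] ^ flip
        geno = gametes[0] + gametes[1]  # 0 = AA, 1 = AB, 2 = BB
        for j, m in enumerate(sub.index):
            columns[m] = geno[:, j]
    coded = pd.DataFrame(columns, index=[f"F2_{i + 1:04d}" for i in range(n)])
    values = decode_genotypes(coded.to_numpy())
    geno_df = pd.DataFrame(values, index=coded.index, columns=coded.columns)
    if config.missing_rate > 0:
        mask = rng.random(geno_df.shape) < config.missing_rate
        geno_df = geno_df.mask(mask)
    gender = pd.Series(rng.permutation(np.arange(n) % 2),
                       index=geno_df.index, name="gender")
    genotypes = F2Genotypes(genotypes=geno_df, gmap=GeneticMap(gmap_table),
                            gender=gender)
    return genotypes, TruthTable()


def _nearest_marker(gmap: GeneticMap, chrom: str, cm: float) -> str:
    sub = gmap.markers_on(chrom)
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    return sub.index[int(np.argmin(np.abs(sub["cm"].to_numpy() - cm)))]


def _dosage(genotypes: F2Genotypes, marker: str,
            rng: np.random.Generator) -> np.ndarray:
    """Additive dosage +1 (AA) / 0 (AB) / -1 (BB); missing imputed at random
    from the F2 prior so simulated effects never leak the missing pattern."""
    from .core import encode_genotypes
    col = encode_genotypes(genotypes.genotypes[[marker]])[:, 0].astype(float)
    miss = col < 0
    if miss.any():
        col[miss] = rng.choice([0, 1, 2], size=miss.sum(),
                               p=[0.25, 0.5, 0.25])
    return 1.0 - col


def simulate_expression(genotypes: F2Genotypes, config: SimulationConfig
                        ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate reporter x individual expression with planted eQTL.

    Hotspot reporters receive an additive effect of the genotype at the
    marker nearest the configured hotspot position; cis reporters an effect
    at their own (random) location; null reporters are noise. All reporters
    get an individual gender offset and Gaussian residual noise.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(genotypes.individuals)
    hs = config.hotspot
    n_genes = hs.n_trans_genes + config.n_cis_genes + config.n_null_genes
    if n_genes <= 0:
        raise ValueError("no reporters configured")
    gmap = genotypes.gmap
    chrom_names = [c.name for c in config.chromosomes]
    mb_per_cm = {c.name: c.mb_per_cm for c in config.chromosomes}
    lengths = {c.name: c.length_cm for c in config.chromosomes}

    hotspot_marker = _nearest_marker(gmap, hs.chromosome, hs.position_cm)
    hotspot_cm = float(gmap.table.loc[hotspot_marker, "cm"])
    hot_dosage = _dosage(genotypes, hotspot_marker, rng)

    gender = genotypes.gender
    if gender is None:
        gender = pd.Series(np.zeros(n, dtype=int), index=genotypes.individuals)
    gender_centered = gender.to_numpy() - gender.to_numpy().mean()

    expr = np.empty((n_genes, n))
    records = []
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    trans_chroms = [c for c in chrom_names if c != hs.chromosome] or chrom_names

    k = 0
    # trans hotspot reporters: gene body on another chromosome
    signs = np.where(rng.random(hs.n_trans_genes) < hs.sign_mix, -1.0, 1.0)
    for i in range(hs.n_trans_genes):
        chrom = trans_chroms[rng.integers(len(trans_chroms))]
        pos_cm = rng.uniform(0, lengths[chrom])
        a = signs[i] * hs.effect * config.residual_sd
        base = a * hot_dosage
        expr[k] = base
        records.append({"gene": gene_ids[k], "kind": "trans_hotspot",
                        "chromosome": chrom, "position_cm": pos_cm,
                        "position_mb": pos_cm * mb_per_cm[chrom],
                        "qtl_chromosome": hs.chromosome, "qtl_cm": hotspot_cm,
                        "effect": a, "driving_marker": hotspot_marker})
        k += 1
    # cis reporters: effect at the gene's own location
    for i in range(config.n_cis_genes):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        pos_cm = rng.uniform(0, lengths[chrom])
        marker = _nearest_marker(gmap, chrom, pos_cm)
        a = config.cis_effect * config.residual_sd
        expr[k] = a * _dosage(genotypes, marker, rng)
        records.append({"gene": gene_ids[k], "kind": "cis",
                        "chromosome": chrom, "position_cm": pos_cm,
                        "position_mb": pos_cm * mb_per_cm[chrom],
                        "qtl_chromosome": chrom,
                        "qtl_cm": float(gmap.table.loc[marker, "cm"]),
                        "effect": a, "driving_marker": marker})
        k += 1
    # null reporters
    for i in range(config.n_null_genes):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        pos_cm = rng.uniform(0, lengths[chrom])
        expr[k] = 0.0
        records.append({"gene": gene_ids[k], "kind": "null",
                        "chromosome": chrom, "position_cm": pos_cm,
                        "position_mb": pos_cm * mb_per_cm[chrom],
                        "qtl_chromosome": None, "qtl_cm": np.nan,
                        "effect": 0.0, "driving_marker": None})
        k += 1

    gender_coef = rng.normal(0.0, config.gender_effect_sd, size=n_genes)
    expr += gender_coef[:, None] * gender_centered[None, :]
    expr += rng.normal(0.0, config.residual_sd, size=expr.shape)

    expr_df = pd.DataFrame(expr, index=gene_ids,
                           columns=genotypes.individuals)
    truth = TruthTable(genes=pd.DataFrame(records).set_index("gene"))
    return expr_df, truth


def signature_score(expr: pd.DataFrame, genes) -> pd.Series:
    """Mean of standardized expression over a reporter set, per individual."""
    sub = expr.loc[list(genes)]
    z = (sub.sub(sub.mean(axis=1), axis=0)).div(sub.std(axis=1, ddof=1), axis=0)
    return z.mean(axis=0)


def simulate_traits(expr: pd.DataFrame, genotypes: F2Genotypes,
                    config: SimulationConfig, truth: TruthTable
                    ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate clinical traits relative to the hotspot transcripts.

    ``causal``: trait = link * standardized signature score + noise, where
    the signature score is the mean of standardized hotspot-reporter
    expressions (the locus reaches the trait only through the transcripts).
    ``reactive``: trait is generated from the hotspot genotype, then its
    ``n_linked`` reporters are re-generated from the trait — ``expr`` is
    updated in place for those rows. ``independent``: trait is generated
    from the hotspot genotype with noise independent of the transcripts.
    """
    if truth.genes is None:
        raise ValueError("expression truth table required")
    rng = np.random.default_rng(config.seed + 2)
    n = len(genotypes.individuals)
    hot_genes = truth.genes.index[truth.genes["kind"] == "trans_hotspot"]
    hotspot_marker = truth.genes.loc[hot_genes[0], "driving_marker"] \
        if len(hot_genes) else None
    traits = {}
    records = []
    # reactive traits rewrite reporters first so the causal signature is
    # computed on the final expression matrix
    reactive_pool = list(hot_genes)
    for spec in config.trait_specs:
        if spec.architecture != "reactive":
            continue
        dosage = _dosage(genotypes, hotspot_marker, rng)
        t = spec.locus_effect * dosage + rng.normal(0, spec.noise_sd, n)
        tz = (t - t.mean()) / t.std(ddof=1)
        linked = reactive_pool[:spec.n_linked]
        reactive_pool = reactive_pool[spec.n_linked:]
        for g in linked:
            expr.loc[g] = (spec.link_coefficient * tz
                           + rng.normal(0, config.residual_sd, n))
        traits[spec.name] = t
        records.append({"trait": spec.name, "architecture": "reactive",
                        "link_coefficient": spec.link_coefficient,
                        "noise_sd": spec.noise_sd,
                        "linked_genes": ",".join(linked)})
    for spec in config.trait_specs:
        if spec.architecture == "reactive":
            continue
        if spec.architecture == "causal":
            score = signature_score(expr, hot_genes).to_numpy()
            scale = score.std(ddof=1)
            score = score / scale if scale > 0 else score
            t = (spec.link_coefficient * score
                 + rng.normal(0, spec.noise_sd, n))
            linked = list(hot_genes)
        elif spec.architecture == "independent":
            dosage = _dosage(genotypes, hotspot_marker, rng)
            t = spec.locus_effect * dosage + rng.normal(0, spec.noise_sd, n)
            linked = list(hot_genes)
        else:  # pragma: no cover - rejected by SimulationConfig
            raise ValueError(f"unknown architecture {spec.architecture!r}")
        traits[spec.name] = t
        records.append({"trait": spec.name, "architecture": spec.architecture,
                        "link_coefficient": spec.link_coefficient,
                        "noise_sd": spec.noise_sd,
                        "linked_genes": ",".join(linked)})
    trait_df = pd.DataFrame(traits, index=genotypes.individuals)
    new_truth = truth.merge(
        TruthTable(traits=pd.DataFrame(records).set_index("trait")))
    return trait_df, new_truth


def simulate_snp_study(config: SimulationConfig
                       ) -> tuple[pd.DataFrame, pd.Index]:
    """Simulate a GWAS SNP universe with a planted-enrichment eSNP subset.

    Non-eSNPs draw association p ~ Uniform(0, 1). Each eSNP falls below
    p = 0.05 with probability ``pi_enriched`` (uniform within the chosen
    side), so the expected sub-threshold fraction of the eSNP set is
    exactly pi.
    """
    spec = config.snp_spec
    if spec.n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if spec.esnp_fraction > 0 and spec.pi_enriched < 0.05:
        warnings.warn("pi < 0.05 requested: eSNP set is depleted, "
                      "not enriched, relative to the uniform null")
    rng = np.random.default_rng(config.seed + 3)
    n = spec.n_snps
    ids = [f"rs{i + 1:07d}" for i in range(n)]
    chrom = rng.integers(1, 23, size=n)
    bp = rng.integers(1, 150_000_000, size=n)
    maf = rng.uniform(*spec.maf_range, size=n)
    distance = rng.exponential(spec.distance_scale_bp, size=n).astype(np.int64)
    is_esnp = rng.random(n) < spec.esnp_fraction
    p = rng.uniform(0, 1, size=n)
    hit = is_esnp & (rng.random(n) < spec.pi_enriched)
    p[hit] = rng.uniform(0, 0.05, size=hit.sum())
    p[is_esnp & ~hit] = rng.uniform(0.05, 1.0, size=(is_esnp & ~hit).sum())
    table = pd.DataFrame({
        "snp": ids, "chromosome": chrom, "bp": bp, "maf": maf,
        "p": p, "distance_bp": distance, "is_esnp": is_esnp,
    }).set_index("snp")
    return table, table.index[is_esnp]


def simulate_modular_expression(n_modules: int = 5, module_size: int = 30,
                                n_noise: int = 100,
                                n_individuals: int = 200,
                                within_r: float = 0.8,
                                seed: int = 0
                                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Block-structured expression for co-expression module benchmarks.

    Each module's reporters load on a shared latent factor so that every
    within-module pair has expected Pearson correlation ``within_r``;
    between-module and noise reporters are independent. Returns the
    reporter x individual matrix and the integer module label per
    reporter (-1 for noise).
    """
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within_r)
    sd = np.sqrt(1.0 - within_r)
    rows, labels = [], []
    for m in range(n_modules):
        factor = rng.normal(size=n_individuals)
        for _ in range(module_size):
            rows.append(lam * factor + sd * rng.normal(size=n_individuals))
            labels.append(m)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_individuals))
        labels.append(-1)
    genes = [f"g{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes), np.array(labels)


@dataclass
class SimulatedStudy:
    genotypes: F2Genotypes
    expression: pd.DataFrame
    traits: pd.DataFrame
    snps: pd.DataFrame
    esnp_ids: pd.Index
    truth: TruthTable
    config: SimulationConfig


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run all four generators in dependency order."""
    genotypes, truth = simulate_f2(config)
    expr, truth = simulate_expression(genotypes, config)
    traits, truth = simulate_traits(expr, genotypes, config, truth)
    snps, esnp_ids = simulate_snp_study(config)
    truth = truth.merge(TruthTable(
        snps=snps[["is_esnp"]].assign(enriched=snps["is_esnp"])))
    return SimulatedStudy(genotypes=genotypes, expression=expr, traits=traits,
                          snps=snps.drop(columns="is_esnp"),
                          esnp_ids=esnp_ids, truth=truth, config=config)
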
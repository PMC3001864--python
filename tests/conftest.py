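"""Shared fixtures: small simulated studies and hand-built containers."""

import numpy as np
import pandas as pd
import pytest

from crossqtl.core import F2Genotypes, GeneticMap, GenotypeProbabilities
from crossqtl.genoprob import genotype_probabilities
from crossqtl.sim import (ChromosomeSpec, HotspotSpec, SimulationConfig,
                          simulate_study)


@pytest.fixture(scope="session")
def small_study():
    """150 individuals, 5 chromosomes, 40 hotspot + 10 cis + 50 null genes."""
    cfg = SimulationConfig(
        n_f2=150,
        chromosomes=tuple(ChromosomeSpec(str(i + 1), 60.0)
                          for i in range(5)) + (ChromosomeSpec("8", 80.0),),
        marker_spacing_cm=5.0,
        hotspot=HotspotSpec(chromosome="8", position_cm=35.0,
                            n_trans_genes=40, effect=1.0, sign_mix=0.25),
        n_cis_genes=10, n_null_genes=50, seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_probs(small_study):
    return genotype_probabilities(small_study.genotypes, step=5.0,
                                  error_rate=0.001)


def hard_genotype_probs(genotypes_int, cm_positions, chromosome="1"):
    """GenotypeProbabilities with one-hot triples from hard genotype calls.

    ``genotypes_int`` is (n_individuals, n_loci) with values 0/1/2.
    """
    g = np.asarray(genotypes_int)
    n, L = g.shape
    probs = np.zeros((n, L, 3))
    probs[np.arange(n)[:, None], np.arange(L)[None, :], g] = 1.0
    loci = pd.DataFrame({
        "locus": [f"m{j}" for j in range(L)],
        "chromosome": chromosome,
        "cm": np.asarray(cm_positions, dtype=float),
        "mb": np.asarray(cm_positions, dtype=float) * 2.0,
        "is_marker": True,
    })
    return GenotypeProbabilities(
        probs=probs, loci=loci,
        individuals=pd.Index([f"i{i}" for i in range(n)]),
        step=0.0, error_rate=0.0)


def two_marker_cross(n, distance_cm, seed=0):
    """Simulated cross with exactly two markers ``distance_cm`` apart."""
    cfg = SimulationConfig(
        n_f2=n,
        chromosomes=(ChromosomeSpec("1", max(distance_cm, 1e-9),
                                    marker_cm=(0.0, distance_cm)),),
        marker_spacing_cm=max(distance_cm, 1.0),
        missing_rate=0.0, seed=seed,
        n_cis_genes=1, n_null_genes=1,
        hotspot=HotspotSpec(chromosome="1", position_cm=0.0, n_trans_genes=1),
    )
    from crossqtl.sim import simulate_f2
    genotypes, _ = simulate_f2(cfg)
    return genotypes
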
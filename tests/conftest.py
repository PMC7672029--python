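import datetime as dt

import numpy as np
import pandas as pd
import pytest

from poolgwas.config import SimConfig, PlantedQTL
from poolgwas.phenology import TemperatureSeries
from poolgwas.qc import GenotypeMatrix


def make_genotype_matrix(values: np.ndarray, scaffolds=None) -> GenotypeMatrix:
    """Wrap a raw (accessions x markers) array as a GenotypeMatrix with
    one-marker-per-scaffold metadata unless scaffolds are given."""
    n_acc, n_mark = values.shape
    scaffolds = scaffolds or [f"scaffold{j + 1}" for j in range(n_mark)]
    markers = pd.DataFrame(
        {
            "marker_id": [f"{s}_{100 + j}" for j, s in enumerate(scaffolds)],
            "scaffold": scaffolds,
            "position": [100 + j for j in range(n_mark)],
            "major": "A",
            "minor": "C",
        }
    )
    return GenotypeMatrix([f"acc{i:03d}" for i in range(n_acc)], markers, values)


def constant_series(temp_c: float, n_days: int = 120,
                    start=dt.date(2013, 4, 1), location="LOC") -> TemperatureSeries:
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    return TemperatureSeries(location, dates, np.full(n_days, float(temp_c)))


@pytest.fixture
def small_sim_config() -> SimConfig:
    """Small structured panel with one planted QTL, fast enough for unit tests."""
    return SimConfig(
        n_accessions=40,
        n_scaffolds=30,
        markers_per_scaffold=(3, 6),
        planted_qtls=[PlantedQTL("FL_Begin", 0.08)],
        seed=7,
    )


def weir_cockerham_fst(genotypes: np.ndarray, pops: np.ndarray) -> float:
    """Independent multi-population Weir-Cockerham theta from per-individual
    diploid dosages (0/1/2), combined over loci as ratio of sums.

    Implements the per-locus a (between-population), b (between individuals
    within population) and c (within-individual) variance components for
    two alleles.
    """
    pops = np.asarray(pops)
    pop_ids = np.unique(pops)
    r = len(pop_ids)
    n_i = np.array([(pops == p).sum() for p in pop_ids], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)

    num = den = 0.0
    for j in range(genotypes.shape[1]):
        gj = genotypes[:, j]
        p_i = np.array([gj[pops == p].mean() / 2.0 for p in pop_ids])
        h_i = np.array([(gj[pops == p] == 1).mean() for p in pop_ids])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        num += a
        den += a + b + c
    return num / den
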
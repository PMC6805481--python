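"""Shared fixtures: tiny pedigrees and a small simulated dataset."""

import numpy as np
import pandas as pd
import pytest

from pigpred.core import GenotypePanel, Pedigree
from pigpred.simpop import SimConfig, TraitSpec, simulate


def make_pedigree(rows):
    """rows: (id, sire, dam) triples; metadata filled with defaults."""
    t = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    t["sex"] = [1 if i % 2 == 0 else 2 for i in range(len(t))]
    t["birth_date"] = "2010-06-15"
    t["population"] = "pop1"
    t["herd"] = "pop1"
    return Pedigree(t)


@pytest.fixture
def trio_pedigree():
    return make_pedigree([("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2")])


@pytest.fixture
def fullsib_mating_pedigree():
    """Full sibs 3 and 4 mated to produce the inbred animal 5."""
    return make_pedigree([("1", "0", "0"), ("2", "0", "0"),
                          ("3", "1", "2"), ("4", "1", "2"), ("5", "3", "4")])


def random_pedigree(n, seed=0, n_founders=10):
    rng = np.random.default_rng(seed)
    rows = [(str(i), "0", "0") for i in range(1, n_founders + 1)]
    for i in range(n_founders + 1, n + 1):
        s, d = rng.integers(1, i, size=2)
        rows.append((str(i), str(s), str(int(d)) if d != s else "0"))
    return make_pedigree(rows)


def random_panel(n, m, seed=0, maf_min=0.1):
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_min, 1 - maf_min, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    markers = pd.DataFrame({
        "marker": [f"m{j}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "a1": "A", "a2": "B",
    })
    return GenotypePanel(ids=[f"id{i}" for i in range(n)], dosages=dos,
                         markers=markers)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset reused across tests (seeded)."""
    cfg = SimConfig(founders_per_pop=40, generations=3, n_seq_markers=800,
                    n_chip_markers=120, n_qtl=30, seed=11)
    return simulate(cfg)
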
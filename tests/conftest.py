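"""Shared fixtures: a hand-buildable toy SNP panel and a small simulated
dataset reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clineseas.matched_controls import build_control_sets
from clineseas.synthetic_data import SimConfig, simulate_dataset
from clineseas.tables_io import InversionDef


def make_toy_panel(
    n: int = 400,
    seed: int = 42,
    n_eqtl: int = 30,
    arms=("2L", "3R"),
    arm_length: int = 30_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame, list[InversionDef]]:
    """A small randomized panel with two arms and one inversion per arm.

    Heterozygosity is restricted to two bins so every occupied match key
    keeps a usable candidate pool at this size.  eQTLs get one gene each
    (several eQTLs may share a gene).
    """
    rng = np.random.default_rng(seed)
    arm = rng.choice(list(arms), size=n)
    pos = np.sort(rng.choice(arm_length, size=n, replace=False))
    het = rng.choice([0.12, 0.31], size=n)
    is_eqtl = np.zeros(n, dtype=bool)
    is_eqtl[rng.choice(n, size=n_eqtl, replace=False)] = True
    snps = pd.DataFrame(
        {
            "snp_id": [f"{a}:{p}" for a, p in zip(arm, pos)],
            "arm": arm,
            "pos": pos,
            "het": het,
            "clinal_p": 1 - rng.random(n),
            "clinal_beta": rng.normal(0, 0.01, n),
            "seasonal_p": 1 - rng.random(n),
            "seasonal_beta": rng.normal(0, 0.02, n),
            "is_eqtl": is_eqtl,
        }
    )
    genes = [f"g{i % 7}" for i in range(n_eqtl)]
    eqtls = pd.DataFrame(
        {
            "snp_id": snps.loc[is_eqtl, "snp_id"].to_numpy(),
            "gene_id": genes,
            "sex_class": rng.choice(
                ["female", "male", "non_sex_biased"], size=n_eqtl
            ),
            "effect_sign": rng.choice([1, -1], size=n_eqtl),
        }
    )
    inversions = [
        InversionDef("In(2L)t", "2L", 2_225_744, 13_154_180),
        InversionDef("In(3R)P", "3R", 12_257_931, 20_569_732),
    ]
    return snps, eqtls, inversions


@pytest.fixture(scope="session")
def toy_panel():
    return make_toy_panel()


@pytest.fixture(scope="session")
def toy_controls(toy_panel):
    snps, _, inversions = toy_panel
    return build_control_sets(snps, inversions, n_sets=20, seed=7)


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete simulated dataset plus its control sets."""
    cfg = SimConfig(
        seed=11,
        n_snps_per_arm=4000,
        n_genes=200,
        eqtls_per_gene=3.0,
        n_pairs=3,
        clinal_enrichment=2.0,
        seasonal_enrichment=1.0,
        concordance_rate=0.8,
    )
    data = simulate_dataset(cfg)
    controls = build_control_sets(data.snps, list(cfg.inversions), n_sets=100, seed=11)
    return data, controls
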
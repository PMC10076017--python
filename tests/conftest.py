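"""Shared fixtures.

Small panels for unit tests are generated fresh per session; the expensive
default-calibration panel and the two simulation studies are session-scoped
so the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nimkit.synthio import PanelConfig, simulate_genotypes
from nimkit.studies import StudyConfig, prepare_panel


SMALL_CFG = PanelConfig(
    n_individuals=300, n_mh_snps=600, n_segments=4, segment_length_bp=30_000,
    nims_per_segment=25, linked_mh_per_segment=10, genome_length_bp=10_000_000,
    seed=7,
)


@pytest.fixture(scope="session")
def small_panel():
    """A ~750-variant panel with 4 introgressed segments, monomorphic sites
    removed (fast unit fixture)."""
    panel, var = simulate_genotypes(SMALL_CFG)
    keep = np.flatnonzero(var["maf"].to_numpy() > 0)
    return panel.subset_variants(keep), var.iloc[keep].reset_index(drop=True)


@pytest.fixture(scope="session")
def toy_variants():
    """Hand-written 10-variant table on two chromosomes."""
    pos = [100, 200, 300, 1000, 2000, 100, 150, 5000, 6000, 7000]
    chrom = ["1"] * 5 + ["2"] * 5
    freq = np.linspace(0.05, 0.45, 10)
    return pd.DataFrame({
        "chrom": chrom, "pos_bp": pos,
        "variant_id": [f"{c}:{p}" for c, p in zip(chrom, pos)],
        "ancestry": ["NIM", "NIM", "MH", "MH", "MH", "NIM", "MH", "MH", "MH", "MH"],
        "allele_freq": freq, "maf": np.minimum(freq, 1 - freq),
    })


@pytest.fixture(scope="session")
def default_prepared():
    """The calibrated default panel with QC, LD scores and both partitions."""
    cfg = StudyConfig(seed=20260131)
    return cfg, prepare_panel(cfg)


@pytest.fixture(scope="session")
def calibration_results(default_prepared):
    from nimkit.studies import run_calibration_study
    cfg, prep = default_prepared
    return run_calibration_study(cfg, prep)


@pytest.fixture(scope="session")
def fdp_results(default_prepared):
    from nimkit.studies import run_fdp_study
    cfg, prep = default_prepared
    return run_fdp_study(cfg, prep)
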
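"""Shared fixtures: one default-scale simulated dataset reused across the
suite (session scoped; generation is deterministic), plus a reduced-scale
simulation config for fast end-to-end pipeline runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from teomics.expression import differential_test
from teomics.simulate import (
    SimulationConfig,
    SubfamilySpec,
    simulate_all,
)

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_ds():
    """Full-scale dataset under generator defaults (the study conditions)."""
    return simulate_all(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_diff(default_ds):
    """Differential expression on the default dataset (TE + gene classes)."""
    ds = default_ds
    te_ids = {t.element_id for t in ds.annotation.tes}
    classes = pd.Series(
        ["te" if f in te_ids else "gene" for f in ds.rna.counts.index],
        index=ds.rna.counts.index,
    )
    return differential_test(ds.rna, feature_classes=classes)


def small_config(seed: int, **overrides) -> SimulationConfig:
    """Reduced-scale config for fast full-pipeline runs (same structure)."""
    kwargs = dict(
        seed=seed,
        genome={"chr1": 3_000_000, "chr2": 3_000_000},
        subfamilies=(
            SubfamilySpec("HERVH-int", "HERVH", "LTR", 150, 2000, 5000),
            SubfamilySpec("HERVK-int", "HERVK", "LTR", 80, 1500, 4000),
            SubfamilySpec("SVA_D", "SVA", "Retroposon", 80, 800, 2500),
            SubfamilySpec("LTR7", "LTR7", "LTR", 40, 400, 500),
            SubfamilySpec("L1HS", "L1", "LINE", 60, 500, 4000),
            SubfamilySpec("AluY", "Alu", "SINE", 60, 280, 320),
        ),
        bound_fraction={
            "HERVH": 0.2, "HERVK": 0.4, "SVA": 0.4, "LTR7": 0.4, "L1": 0.05, "Alu": 0.0,
        },
        n_genes=280,
        n_znf=150,
        n_znf_de=10,
        n_cpgs=40_000,
        n_icr_maternal=29,
        n_dmr=10,
        n_background_peaks=300,
        n_gained_te=20,
        n_gained_background=30,
        n_lost_background=10,
        n_closed_promoters=25,
        n_opened_promoters=10,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
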
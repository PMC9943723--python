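import numpy as np
import pandas as pd
import pytest

from cnvphewas.cnv_matrix import CnvMatrix
from cnvphewas.simulate import MrSpec, PlantedEffect, SimConfig


@pytest.fixture
def small_config():
    """Small but non-trivial simulation: inflated frequencies, mixed effects."""
    return SimConfig(
        n_samples=2000,
        n_probes=80,
        seed=42,
        planted_effects=[
            PlantedEffect("trait_u", "continuous", "U-shape", 1.0, (18_700_000, 21_800_000)),
            PlantedEffect("trait_m", "continuous", "mirror", -0.6, (18_700_000, 20_400_000)),
            PlantedEffect("trait_null", "continuous", "mirror", 0.0, (18_700_000, 21_800_000)),
            PlantedEffect("disease", "binary", "duplication-only", 1.2, (18_700_000, 20_400_000)),
        ],
        mr_spec=MrSpec(genes=("GENE1",), n_ivs=20, causal_effect=0.3),
    )


def toy_matrix(states, bp=None, samples=None):
    """Build a CnvMatrix from a raw (probes x samples) state array."""
    states = np.asarray(states, dtype=float)
    n_p, n_s = states.shape
    if bp is None:
        bp = 1000 * (np.arange(n_p) + 1)
    if samples is None:
        samples = [f"s{j}" for j in range(n_s)]
    return CnvMatrix(
        probe_ids=[f"p{i}" for i in range(n_p)],
        probe_bp=np.asarray(bp, dtype=np.int64),
        sample_ids=list(samples),
        states=states,
    )


@pytest.fixture
def carrier_matrix():
    """50-probe x 5000-sample matrix with block-structured rare carriers.

    Two perfectly-correlated probe blocks (probes 0-24 and 25-49), with 1%
    duplication and 0.5% deletion carriers in each block, mimicking
    recurrent CNVs that span many probes.
    """
    rng = np.random.default_rng(2024)
    n_s = 5000
    states = np.zeros((50, n_s))
    for block, sl in ((0, slice(0, 25)), (1, slice(25, 50))):
        u = rng.uniform(size=n_s)
        dup = u < 0.01
        dele = (u >= 0.01) & (u < 0.015)
        states[sl, dup] = 1.0
        states[sl, dele] = -1.0
    return toy_matrix(states)
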
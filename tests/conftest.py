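import numpy as np
import pandas as pd
import pytest

from fppfm.io_data import GenotypeTable, PhenotypeSeries
from fppfm.simulation_study import SimConfig


def make_phenos(Y: np.ndarray, stage_ids, days_per_stage: int,
                trait_id="trait", individuals=None) -> PhenotypeSeries:
    """Wrap an (n, S*T) matrix as a long-format PhenotypeSeries."""
    n, M = Y.shape
    assert M == len(stage_ids) * days_per_stage
    individuals = individuals or [f"I{i:03d}" for i in range(n)]
    days = np.arange(M)
    stages = np.repeat(stage_ids, days_per_stage)
    df = pd.DataFrame(
        {
            "individual_id": np.repeat(individuals, M),
            "trait_id": trait_id,
            "stage_id": np.tile(stages, n),
            "day": np.tile(days, n),
            "value": Y.ravel(),
        }
    )
    return PhenotypeSeries(df, list(stage_ids))


def sad_noise(rng, n, M, rho, phi2):
    """Draw SAD(1) residuals by the AR recursion eps_t = rho eps_{t-1} + eta_t."""
    eta = rng.standard_normal((n, M)) * np.sqrt(phi2)
    eps = np.empty_like(eta)
    eps[:, 0] = eta[:, 0]
    for t in range(1, M):
        eps[:, t] = rho * eps[:, t - 1] + eta[:, t]
    return eps


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_config():
    return SimConfig(n_individuals=60, n_markers=50, heritability=0.10,
                     correlated=True, rho_sim=0.6)


@pytest.fixture
def toy_genotypes():
    """5 markers x 4 individuals on one chromosome; markers 1 and 2 identical."""
    codes = np.array(
        [
            [0, 0, 2, 2],
            [0, 2, 0, 2],
            [0, 2, 0, 2],
            [2, 2, 0, 0],
            [0, 0, 0, 2],
        ],
        dtype=float,
    )
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(5)],
            "chromosome": "chr1",
            "position_cM": [0.0, 1.0, 2.0, 3.0, 4.0],
        }
    )
    return GenotypeTable(markers, ["a", "b", "c", "d"], codes)
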
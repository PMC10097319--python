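"""Shared fixtures.

The two session-scoped ensembles (stationary control and moving-band
warming scenario) are the workhorses of the end-to-end checks: 100x100
cells at 0.25 degrees, 30 yearly steps, 10 simulations each, everything
generated from seeds at test time.
"""

from __future__ import annotations

import numpy as np
import pytest

import invasim as iv

START, END = 2020, 2049  # 30 yearly steps
N_SIMS = 10


def small_grid(n: int = 10, res: float = 0.25, lon0: float = -110.0,
               lat0: float = 40.0) -> iv.GridSpec:
    return iv.GridSpec(res, lon0, lat0, n, n)


@pytest.fixture
def grid10() -> iv.GridSpec:
    return small_grid(10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)


def _run_preset(name: str, seed: int) -> tuple[iv.EnsembleResult, iv.ScenarioLayers]:
    import dataclasses

    cfg = dataclasses.replace(iv.preset(name), seed=seed)
    provider = iv.ScenarioLayers(cfg, START, END, bcl_window=30)
    occ = iv.synth_occurrences(cfg, provider.static)
    sim = iv.SimulationConfig(start_year=START, end_year=END,
                              n_simulations=N_SIMS, seed=seed)
    return iv.run_ensemble(occ, provider, sim), provider


@pytest.fixture(scope="session")
def stationary_ensemble() -> iv.EnsembleResult:
    ens, _ = _run_preset("stationary", seed=11)
    return ens


@pytest.fixture(scope="session")
def moving_band_ensemble() -> iv.EnsembleResult:
    ens, _ = _run_preset("moving_band", seed=12)
    return ens


def per_sim_centroid_lat(ensemble: iv.EnsembleResult, period) -> np.ndarray:
    """Per-simulation mean latitude of cells invaded during the period."""
    g = ensemble.grid
    out = []
    for rec in ensemble.records:
        cells = iv.period_cells(rec, period, ensemble.years)
        r, _ = np.divmod(cells, g.n_cols)
        out.append(g.center_of(r, np.zeros_like(r))[1].mean())
    return np.asarray(out)
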
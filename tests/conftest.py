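"""Shared fixtures: small planted atlases reused across the suite.

Session-scoped where generation is expensive; every fixture is a pure
function of a fixed seed so the suite is deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import pathmotif as pm
from pathmotif.dispersion import build_embedding
from pathmotif.pipeline import PipelineConfig, integrate_datasets

warnings.filterwarnings("ignore", category=UserWarning)

PATHWAY_GENES = [f"PWG{i:03d}" for i in range(11)]


def toy_pathway(name: str = "toy") -> pm.PathwayDefinition:
    return pm.PathwayDefinition(name, list(PATHWAY_GENES))


def make_atlas(
    seed: int,
    n_states: int = 300,
    n_clades: int = 5,
    n_profiles: int = 6,
    motif_fraction: float = 0.5,
    cells_per_state: int = 8,
    n_background: int = 200,
    **truth_kwargs,
):
    """Generate a planted atlas and run it through integration."""
    truth = pm.simulate_truth(
        n_states=n_states,
        n_clades=n_clades,
        n_profiles=n_profiles,
        n_genes=11,
        motif_fraction=motif_fraction,
        seed=seed,
        **truth_kwargs,
    )
    datasets = pm.emit_single_cell_datasets(
        truth, n_datasets=3, cells_per_state=cells_per_state,
        n_background=n_background,
    )
    cfg = PipelineConfig(cluster_by="state", seed=seed)
    states, emb50 = integrate_datasets(datasets, cfg)
    return truth, datasets, states, emb50


@pytest.fixture(scope="session")
def atlas():
    """One medium planted atlas shared by many tests (seed 1, K=6)."""
    truth, datasets, states, emb50 = make_atlas(seed=1)
    return {"truth": truth, "datasets": datasets, "states": states, "emb50": emb50}


@pytest.fixture(scope="session")
def scaled(atlas):
    return pm.scale_pathway(atlas["states"], toy_pathway())


@pytest.fixture(scope="session")
def emb100(atlas):
    return build_embedding(atlas["states"], n_pc=100, seed=1)


@pytest.fixture(scope="session")
def labeling(scaled):
    return pm.cluster_profiles(scaled, 6)


def truth_profile_of(states) -> pd.Series:
    """Planted profile index per pseudo-bulk state (−1 = pathway off)."""
    return states.state_meta["profile_truth"].astype(int)


def toy_state_matrix(values: np.ndarray, genes=None, meta=None):
    """Wrap a plain array as a CellStateMatrix for unit tests."""
    from pathmotif.integration import CellStateMatrix

    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    index = [f"s{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=index, columns=genes)
    m = meta if meta is not None else pd.DataFrame(index=index)
    m.index = df.index
    return CellStateMatrix(df, m)
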
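"""Motif vs private classification via transcriptome-space dispersion.

The dispersion of a group of cell states is the mean pairwise Euclidean
distance between them in a 100-component PCA of the 4,000 most variable
genes. Its expectation for *closely related* states (the lower bound) comes
from cutting the global transcriptome dendrogram — cosine distance in a
20-component PC space — into the same number k of groups; its expectation
for *arbitrary* states (the upper bound) comes from shuffling profile labels
while preserving group sizes. A profile is a motif when its dispersion
exceeds the 90th percentile of the lower bound, private when it falls below
the lower bound's median, intermediate otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from ._cluster import cosine_distance_matrix, hierarchical_labels
from .integration import CellStateMatrix, EmbeddingSpace, embed_states
from .profiles import ProfileLabeling

log = logging.getLogger(__name__)

MOTIF_PERCENTILE = 90.0
PRIVATE_PERCENTILE = 50.0
TREE_N_PC = 20  # PC subspace used only to build the global dendrogram


@dataclass
class DispersionReport:
    """Per-profile dispersion, null distributions, and classification."""

    table: pd.DataFrame  # profile, n_states, dispersion, class
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    motif_threshold: float  # P90 of lower bound
    private_threshold: float  # P50 of lower bound

    def to_json(self, path: str | Path) -> None:
        d = {
            "profiles": self.table.replace({np.nan: None}).to_dict("records"),
            "lower_bound": self.lower_bound.tolist(),
            "upper_bound": self.upper_bound.tolist(),
            "motif_threshold": self.motif_threshold,
            "private_threshold": self.private_threshold,
        }
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass
class MotifTable:
    """Contingency tables of profile membership by organ and cell class."""

    by_organ: pd.DataFrame
    by_cell_class: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.by_organ.sum(axis=1)


def build_embedding(
    m: CellStateMatrix, n_hvg: int = 4000, n_pc: int = 100, seed: int = 0
) -> EmbeddingSpace:
    """Transcriptome embedding used for dispersion: 4,000 HVGs, 100 PCs."""
    return embed_states(m, n_hvg=n_hvg, n_pc=n_pc, seed=seed)


def _group_dispersion(coords: np.ndarray) -> float:
    """Mean pairwise Euclidean distance among rows; NaN for <2 rows."""
    if coords.shape[0] < 2:
        return np.nan
    return float(pdist(coords).mean())


def profile_dispersion(
    labels: ProfileLabeling, emb: EmbeddingSpace
) -> pd.Series:
    """Dispersion of each profile's member states in the embedding.

    Singleton profiles have undefined dispersion (NaN) and are excluded
    from classification downstream.
    """
    coords = emb.coords_frame()
    out = {}
    for profile in sorted(labels.labels.unique()):
        members = labels.members(profile)
        out[profile] = _group_dispersion(coords.loc[members].to_numpy())
        if len(members) < 2:
            log.warning("profile %d is a singleton; dispersion undefined", profile)
    return pd.Series(out, name="dispersion")


def lower_bound_distribution(
    emb: EmbeddingSpace, k_opt: int, tree_n_pc: int = TREE_N_PC
) -> np.ndarray:
    """Dispersions of k_opt groups of transcriptomically related states.

    The global dendrogram is built with cosine distances in the leading
    ``tree_n_pc`` PCs and cut into k_opt groups; each group's dispersion is
    still measured as Euclidean distance in the full embedding.
    """
    n = emb.pc_coords.shape[0]
    if k_opt > n:
        raise ValueError(f"k_opt={k_opt} exceeds {n} states")
    tree_coords = emb.pc_coords[:, : min(tree_n_pc, emb.n_pc)]
    dist = cosine_distance_matrix(tree_coords)
    groups, _ = hierarchical_labels(dist, k_opt)
    values = [
        _group_dispersion(emb.pc_coords[groups == g]) for g in np.unique(groups)
    ]
    values = np.array([v for v in values if np.isfinite(v)])
    if values.size == 0:
        raise ValueError("all lower-bound groups are singletons; k_opt too large")
    return values


def upper_bound_distribution(
    labels: ProfileLabeling,
    emb: EmbeddingSpace,
    n_rand: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Dispersions of randomly relabeled groups (profile sizes preserved)."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    coords = emb.coords_frame().loc[labels.labels.index].to_numpy()
    lab = labels.labels.to_numpy()
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_rand):
        perm = rng.permutation(lab)
        for g in np.unique(perm):
            v = _group_dispersion(coords[perm == g])
            if np.isfinite(v):
                pooled.append(v)
    return np.array(pooled)


def classify_profiles(
    dispersions: pd.Series,
    lower_bound: np.ndarray,
    upper_bound: np.ndarray,
    labels: ProfileLabeling | None = None,
    motif_percentile: float = MOTIF_PERCENTILE,
    private_percentile: float = PRIVATE_PERCENTILE,
) -> DispersionReport:
    """Label each profile motif / private / intermediate.

    motif ⇔ dispersion > P90(lower bound); private ⇔ dispersion <
    P50(lower bound); both comparisons strict; undefined (singleton)
    dispersions stay unclassified.
    """
    if lower_bound.size == 0:
        raise ValueError("empty lower-bound distribution")
    p90 = float(np.percentile(lower_bound, motif_percentile))
    p50 = float(np.percentile(lower_bound, private_percentile))
    rows = []
    for profile, d in dispersions.items():
        if not np.isfinite(d):
            cls = "unclassified"
        elif d > p90:
            cls = "motif"
        elif d < p50:
            cls = "private"
        else:
            cls = "intermediate"
        n_states = int((labels.labels == profile).sum()) if labels is not None else -1
        rows.append(
            {"profile": profile, "n_states": n_states, "dispersion": d, "class": cls}
        )
    return DispersionReport(pd.DataFrame(rows), lower_bound, upper_bound, p90, p50)


def motif_tissue_table(
    labels: ProfileLabeling, state_meta: pd.DataFrame
) -> MotifTable:
    """Profile × organ and profile × cell-class membership counts."""
    meta = state_meta.reindex(labels.labels.index)
    organ = meta["organ"] if "organ" in meta else pd.Series("unknown", index=meta.index)
    cclass = (
        meta["cell_class"] if "cell_class" in meta
        else pd.Series("unknown", index=meta.index)
    )
    organ = organ.fillna("unknown")
    cclass = cclass.fillna("unknown")
    return MotifTable(
        by_organ=pd.crosstab(labels.labels, organ),
        by_cell_class=pd.crosstab(labels.labels, cclass),
    )
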
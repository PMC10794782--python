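"""Pathway expression profiles: q95 MinMax scaling, on/off gating, clustering.

Each pathway gene is rescaled to [0, 1] against its 95th-percentile
expression across all cell states, so genes with very different dynamic
ranges weigh equally. A state is "on" for the pathway when at least two
pathway genes exceed 0.3 on that scale; on-states are clustered
hierarchically (complete linkage by default) on pairwise cosine distances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from ._cluster import cosine_distance_matrix, hierarchical_labels
from .integration import CellStateMatrix

log = logging.getLogger(__name__)

ON_THRESHOLD = 0.3
MIN_GENES_ON = 2
SCALE_QUANTILE = 0.95
MIN_PATHWAY_GENES = 7


@dataclass
class PathwayDefinition:
    """A named, ordered gene list with optional per-gene role tags."""

    name: str
    genes: list[str]
    roles: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in pathway {self.name}")
        if len(self.genes) < MIN_PATHWAY_GENES:
            raise ValueError(
                f"pathway {self.name} has {len(self.genes)} genes; "
                f"at least {MIN_PATHWAY_GENES} required"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayDefinition":
        d = json.loads(Path(path).read_text())
        return cls(d["name"], list(d["genes"]), d.get("roles", {}), d.get("source", ""))

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "PathwayDefinition":
        """Two-column TSV (gene, optional role); header optional."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        first = str(df.iloc[0, 0]).lower()
        if first in ("gene", "gene_name", "symbol"):
            df = df.iloc[1:]
        genes = df.iloc[:, 0].tolist()
        roles = (
            dict(zip(genes, df.iloc[:, 1].fillna("").tolist()))
            if df.shape[1] > 1
            else {}
        )
        return cls(name or Path(path).stem, genes, roles)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"name": self.name, "genes": self.genes, "roles": self.roles,
                 "source": self.source},
                indent=1,
            )
        )


@dataclass
class ScaledPathwayMatrix:
    """Per-gene q95-scaled pathway submatrix over all states, plus on-mask."""

    values: pd.DataFrame  # states × genes in [0, 1]
    scale_factors: pd.Series  # per-gene q95 denominators
    on_mask: pd.Series  # per-state bool
    threshold: float = ON_THRESHOLD
    min_genes_on: int = MIN_GENES_ON
    missing_genes: list[str] = field(default_factory=list)
    quantile: float = SCALE_QUANTILE

    @property
    def on_values(self) -> pd.DataFrame:
        return self.values.loc[self.on_mask]

    @property
    def n_on(self) -> int:
        return int(self.on_mask.sum())


@dataclass
class ProfileLabeling:
    """Profile ids (1..k) for the on-states, plus the merge tree."""

    labels: pd.Series  # index: on-state ids; values: 1..k
    linkage: np.ndarray
    k: int

    def members(self, profile: int) -> pd.Index:
        return self.labels.index[self.labels == profile]


def scale_pathway(
    m: CellStateMatrix,
    pw: PathwayDefinition,
    quantile: float = SCALE_QUANTILE,
    threshold: float = ON_THRESHOLD,
    min_genes_on: int = MIN_GENES_ON,
) -> ScaledPathwayMatrix:
    """MinMax-scale each pathway gene to its q95 across *all* states.

    scaled = clip(x / q95(x), 0, 1), with the quantile taken by linear
    interpolation over every state (before any on/off gating). All-zero
    genes scale to all-zero columns; genes absent from the matrix are
    reported and dropped.
    """
    present = [g for g in pw.genes if g in m.values.columns]
    missing = [g for g in pw.genes if g not in m.values.columns]
    if missing:
        log.warning("pathway %s: %d genes missing from matrix: %s",
                    pw.name, len(missing), missing)
    if not present:
        raise ValueError(f"no pathway {pw.name} genes present in the matrix")
    sub = m.values[present].to_numpy(dtype=float)
    q95 = np.quantile(sub, quantile, axis=0)  # linear interpolation
    denom = np.where(q95 > 0, q95, 1.0)  # all-zero genes stay zero
    scaled = np.clip(sub / denom[None, :], 0.0, 1.0)
    values = pd.DataFrame(scaled, index=m.values.index, columns=present)
    on = pd.Series(
        (scaled >= threshold).sum(axis=1) >= min_genes_on, index=m.values.index
    )
    return ScaledPathwayMatrix(
        values, pd.Series(q95, index=present), on, threshold, min_genes_on, missing,
        quantile,
    )


def pathway_on_mask(
    p: ScaledPathwayMatrix,
    threshold: float | None = None,
    min_genes_on: int | None = None,
) -> pd.Series:
    """Recompute the on-mask: ≥ ``min_genes_on`` genes at ≥ ``threshold``."""
    t = p.threshold if threshold is None else threshold
    g = p.min_genes_on if min_genes_on is None else min_genes_on
    return (p.values >= t).sum(axis=1) >= g


def cluster_profiles(
    p: ScaledPathwayMatrix, k: int, linkage_method: str = "complete"
) -> ProfileLabeling:
    """Cut the cosine-distance dendrogram of on-states into exactly k profiles."""
    on = p.on_values
    if on.shape[0] == 0:
        raise ValueError("no on-states: nothing to cluster")
    if not 2 <= k <= on.shape[0]:
        raise ValueError(f"k={k} outside [2, {on.shape[0]}]")
    x = on.to_numpy(dtype=float)
    if (np.linalg.norm(x, axis=1) == 0).any():
        raise ValueError("zero row among on-states; on-filter violated")
    dist = cosine_distance_matrix(x)
    labels, z = hierarchical_labels(dist, k, method=linkage_method)
    return ProfileLabeling(pd.Series(labels + 1, index=on.index), z, k)


def gene_prevalence(
    p: ScaledPathwayMatrix, threshold: float = ON_THRESHOLD
) -> pd.Series:
    """Per gene: number of on-states expressing it at ≥ ``threshold``."""
    on = p.on_values
    return (on >= threshold).sum(axis=0).astype(int)


def gene_pair_correlations(
    p: ScaledPathwayMatrix,
    subset: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation for every gene pair over a subset of states.

    Significance is Benjamini–Hochberg-adjusted at ``alpha``. Pairs
    involving a constant gene get NaN correlation and are flagged
    undefined rather than significant.
    """
    states = p.on_values if subset is None else p.values.loc[subset]
    if states.shape[0] < 3:
        raise ValueError("need at least 3 states for correlations")
    genes = list(states.columns)
    x = states.to_numpy(dtype=float)
    constant = x.std(axis=0) == 0
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if constant[i] or constant[j]:
                rows.append((genes[i], genes[j], np.nan, np.nan))
            else:
                rho, pval = spearmanr(x[:, i], x[:, j])
                rows.append((genes[i], genes[j], rho, pval))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "pval"])
    defined = df["pval"].notna()
    qvals = np.full(len(df), np.nan)
    if defined.any():
        qvals[defined.to_numpy()] = multipletests(
            df.loc[defined, "pval"], method="fdr_bh"
        )[1]
    df["qval"] = qvals
    df["significant"] = df["qval"] < alpha
    df.loc[~defined, "significant"] = False
    df["undefined"] = ~defined
    return df
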
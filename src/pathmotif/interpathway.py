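"""Inter-pathway coupling (adjusted mutual information) and trajectory matching.

For coupling, every pathway's profile labeling is extended to the full set
of integrated cell states with label 0 for "pathway off", and each pair of
pathways is scored by the adjusted mutual information (AMI) between those
full labelings: 0 is the chance expectation, 1 is perfect dependence.

For trajectories, a staged developmental dataset is quantile-rescaled onto
the integrated atlas's per-gene [0, 1] scale, averaged per stage, and each
stage's mean pathway profile is matched to its nearest reference profile
centroid under cosine distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score

from .profiles import ProfileLabeling, ScaledPathwayMatrix

log = logging.getLogger(__name__)

OFF_LABEL = 0


@dataclass
class TrajectoryProfileTrack:
    """Per-stage mean profiles with their nearest reference profile."""

    stage_means: pd.DataFrame  # stage × pathway genes, stage order preserved
    matched_profile: pd.Series  # per stage
    match_distance: pd.Series  # per stage


def extend_labels(
    labels: ProfileLabeling, on_mask: pd.Series, all_states: pd.Index | None = None
) -> pd.Series:
    """Extend on-state profile ids to all states, label 0 where pathway is off."""
    index = on_mask.index if all_states is None else pd.Index(all_states)
    if (~on_mask.reindex(labels.labels.index, fill_value=False)).any():
        raise ValueError("labeled state marked off: labels inconsistent with mask")
    full = pd.Series(OFF_LABEL, index=index, dtype=int)
    if len(labels.labels):
        full.loc[labels.labels.index] = labels.labels.astype(int)
    return full


def pairwise_ami(
    labelings: dict[str, pd.Series] | list[pd.Series],
    average_method: str = "max",
) -> pd.DataFrame:
    """Symmetric pathway × pathway AMI matrix with unit diagonal.

    All labelings must cover the same states. Two constant labelings are the
    same one-block partition, hence AMI 1 by convention.
    """
    if isinstance(labelings, list):
        labelings = {f"pathway{i}": s for i, s in enumerate(labelings)}
    names = list(labelings)
    if len(names) < 2:
        raise ValueError("need at least two labelings")
    index = labelings[names[0]].index
    for n in names[1:]:
        if not labelings[n].index.equals(index):
            raise ValueError(f"labeling {n} covers a different state set")
    mat = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mat[i, j] = mat[j, i] = adjusted_mutual_info_score(
                labelings[names[i]], labelings[names[j]],
                average_method=average_method,
            )
    return pd.DataFrame(mat, index=names, columns=names)


def rescale_to_reference(
    dev_values: pd.DataFrame,
    reference: ScaledPathwayMatrix,
    quantile: float | None = None,
) -> pd.DataFrame:
    """Map developmental expression onto the integrated atlas's [0, 1] scale.

    Per gene, an affine map sends the developmental data's [q0, q95] range
    onto [0, 1] (the integrated gene's scaled range), then clips. Genes
    without a reference scale factor are dropped with a report; constant
    (all-equal) genes map to zero.
    """
    q = reference.quantile if quantile is None else quantile
    shared = [g for g in dev_values.columns if g in reference.scale_factors.index]
    missing = [g for g in dev_values.columns if g not in reference.scale_factors.index]
    if missing:
        log.warning("%d genes missing from reference scale, dropped: %s",
                    len(missing), missing)
    if not shared:
        raise ValueError("no overlap between developmental genes and reference")
    x = dev_values[shared].to_numpy(dtype=float)
    q0 = np.quantile(x, 0.0, axis=0)
    q95 = np.quantile(x, q, axis=0)
    span = q95 - q0
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((x - q0[None, :]) / safe[None, :], 0.0, 1.0)
    scaled[:, span <= 0] = 0.0
    return pd.DataFrame(scaled, index=dev_values.index, columns=shared)


def stage_mean_profiles(
    cells: pd.DataFrame, stage_labels: pd.Series
) -> pd.DataFrame:
    """Mean profile per stage, preserving stage order of first appearance.

    ``stage_labels`` may be an ordered categorical; otherwise stages keep
    sorted order. Empty stages are flagged with a warning and omitted.
    """
    stage_labels = stage_labels.reindex(cells.index)
    if stage_labels.isna().any():
        raise ValueError("every cell needs a stage label")
    if isinstance(stage_labels.dtype, pd.CategoricalDtype):
        order = [s for s in stage_labels.cat.categories]
        empty = [s for s in order if (stage_labels == s).sum() == 0]
        if empty:
            warnings.warn(f"empty stages omitted: {empty}")
        order = [s for s in order if s not in empty]
    else:
        order = sorted(stage_labels.unique())
    means = cells.groupby(stage_labels, observed=True).mean()
    return means.loc[order]


def profile_centroids(
    p: ScaledPathwayMatrix, labels: ProfileLabeling
) -> pd.DataFrame:
    """Mean scaled profile of each reference profile's member states."""
    return p.on_values.groupby(labels.labels).mean()


def match_nearest_profile(
    stage_profile: pd.Series | np.ndarray,
    reference_profiles: pd.DataFrame,
    metric: str = "cosine",
) -> tuple[int, float]:
    """Nearest reference centroid to one profile; ties go to the smaller id."""
    if reference_profiles.shape[0] == 0:
        raise ValueError("empty reference profile set")
    v = np.asarray(stage_profile, dtype=float)
    refs = reference_profiles.to_numpy(dtype=float)
    if metric == "cosine":
        vn = np.linalg.norm(v)
        rn = np.linalg.norm(refs, axis=1)
        sim = (refs @ v) / (np.where(rn > 0, rn, 1.0) * (vn if vn > 0 else 1.0))
        d = 1.0 - sim
    elif metric == "euclidean":
        d = np.linalg.norm(refs - v[None, :], axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = np.round(d, 12)  # deterministic ties under float noise
    best = np.flatnonzero(d == d.min())
    if len(best) > 1:
        warnings.warn("tie in nearest-profile match; smallest profile id wins")
    idx = best[0]
    return int(reference_profiles.index[idx]), float(d[idx])


def match_trajectory(
    stage_means: pd.DataFrame,
    reference_profiles: pd.DataFrame,
    metric: str = "cosine",
) -> TrajectoryProfileTrack:
    """Match every stage's mean profile to its nearest reference profile."""
    genes = [g for g in reference_profiles.columns if g in stage_means.columns]
    if not genes:
        raise ValueError("no shared genes between stages and reference profiles")
    matches, dists = [], []
    for _, row in stage_means[genes].iterrows():
        m, d = match_nearest_profile(row, reference_profiles[genes], metric)
        matches.append(m)
        dists.append(d)
    return TrajectoryProfileTrack(
        stage_means,
        pd.Series(matches, index=stage_means.index, name="matched_profile"),
        pd.Series(dists, index=stage_means.index, name="match_distance"),
    )
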
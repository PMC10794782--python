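"""Synthetic multi-dataset single-cell atlases with planted pathway profiles.

The generator builds (i) a latent "cell-type tree": clade centroids placed
mutually equidistant in a latent transcriptome space, with per-state
isotropic noise; (ii) a set of K planted pathway profiles in [0, 1], some
assigned across at least three distant clades ("motif" truth) and some
confined to a single clade ("private" truth); (iii) raw count matrices for
several pseudo-datasets with negative-binomial count noise, background genes
driven by the latent coordinates so transcriptome clustering can recover the
clades, and partially overlapping gene sets; and (iv) a toy staged
trajectory whose pathway profile is stable, fades in amplitude, or switches
between two planted profiles at a known stage.

Everything is a pure function of its seed: regenerating with the same seed
is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

OFF = -1  # assignment value for states with the pathway off


@dataclass
class CladeTree:
    """Latent cell-type tree: clade centroids plus per-state coordinates."""

    latent_coords: np.ndarray  # (n_states, d_lat)
    clade_id: np.ndarray  # (n_states,) int
    centroids: np.ndarray  # (n_clades, d_lat)
    nodes: np.ndarray  # scipy linkage over states (the state dendrogram)
    separation: float
    noise_sd: float
    seed: int

    @property
    def n_states(self) -> int:
        return self.latent_coords.shape[0]

    @property
    def n_clades(self) -> int:
        return self.centroids.shape[0]


@dataclass
class PlantedProfileSet:
    """K planted pathway profiles with motif/private truth and assignments."""

    profiles: np.ndarray  # (K, Ng) in [0, 1]
    class_truth: list[str]  # per profile: "motif" | "private"
    assignment: np.ndarray  # (n_states,) profile index, OFF for off states
    amplitude: np.ndarray = None  # (n_states,) per-state expression amplitude
    private_clade: dict[int, int] = field(default_factory=dict)
    ambiguous: bool = False  # single-profile degenerate case

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_genes(self) -> int:
        return self.profiles.shape[1]


@dataclass
class NoiseParams:
    depth: float = 3000.0  # mean counts per cell
    dispersion: float = 0.1  # NB dispersion alpha; 0 → Poisson
    seed: int = 0


@dataclass
class SyntheticTruth:
    tree: CladeTree
    planted: PlantedProfileSet
    noise_params: NoiseParams


@dataclass
class TrajectorySim:
    """Staged cells with per-stage truth profile index and amplitude."""

    adata: ad.AnnData  # obs: "stage" (int), ordered by stage
    truth_profile: np.ndarray  # (n_stages,) planted profile index per stage
    truth_amplitude: np.ndarray  # (n_stages,)
    dynamics: str
    switch_stage: int | None = None


def generate_clade_tree(
    n_states: int,
    n_clades: int,
    separation: float,
    d_lat: int = 10,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> CladeTree:
    """Place ``n_clades`` mutually separated centroids and scatter states.

    Centroids are mutually orthogonal directions of equal norm, so every
    pair is exactly ``separation`` apart; states get a centroid plus
    isotropic Gaussian noise of scale ``noise_sd``. Clade sizes are as even
    as possible and every clade is non-empty.
    """
    if n_states < n_clades:
        raise ValueError(f"n_states={n_states} < n_clades={n_clades}")
    if n_clades < 2:
        raise ValueError("need at least 2 clades")
    if separation <= 0:
        raise ValueError("separation must be positive")
    d = max(d_lat, n_clades)
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((d, n_clades)))
    centroids = q.T * (separation / np.sqrt(2.0))
    clade_id = rng.permutation(np.arange(n_states) % n_clades)
    coords = centroids[clade_id] + noise_sd * rng.standard_normal((n_states, d))
    nodes = linkage(pdist(coords), method="average")
    return CladeTree(coords, clade_id, centroids, nodes, separation, noise_sd, seed)


def _sample_profile(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    """One profile: a small combinatorial set of strongly expressed genes.

    Real pathway profiles are dominated by a few components (2–4 of ~11)
    over a near-zero floor; this sparse family keeps distinct profiles far
    apart in cosine space so the planted profile count is identifiable.
    """
    n_high = int(rng.integers(2, min(5, n_genes // 2 + 1)))
    high = rng.choice(n_genes, size=n_high, replace=False)
    prof = rng.uniform(0.0, 0.1, size=n_genes)
    prof[high] = rng.uniform(0.7, 1.0, size=n_high)
    return prof


def _min_cosine_distance(prof: np.ndarray, others: list[np.ndarray]) -> float:
    if not others:
        return np.inf
    o = np.vstack(others)
    sims = (o @ prof) / (np.linalg.norm(o, axis=1) * np.linalg.norm(prof))
    return float(1.0 - sims.max())


def plant_profiles(
    n_profiles: int,
    n_genes: int,
    n_states: int,
    tree: CladeTree,
    motif_fraction: float = 0.5,
    seed: int = 0,
    off_fraction: float = 0.15,
    min_profile_distance: float = 0.5,
    usage_skew: float = 0.5,
    amplitude_range: tuple[float, float] = (0.5, 1.0),
) -> PlantedProfileSet:
    """Plant K separable profiles and assign them to states on the tree.

    ``round(motif_fraction * K)`` profiles are motifs, assigned across at
    least three distinct clades; the rest are private, each confined to one
    clade (distinct clades per private profile). A random ``off_fraction``
    of states carries no profile at all. Profiles are rejection-sampled to a
    minimum pairwise cosine distance so the planted K is identifiable, and
    every profile has at least two genes ≥ 0.3 so assigned states pass the
    on-filter.

    Profile usage is deliberately skewed (motif m is used proportionally to
    ``usage_skew**m``): real profile memberships are strongly unequal, and
    a dominant profile is what gives the silhouette curve a sharp drop just
    past the true cluster count. Each assigned state also draws an overall
    expression amplitude from ``amplitude_range``, emulating the graded
    pathway expression levels seen across real cell states.
    """
    if n_profiles < 1:
        raise ValueError("need at least one profile")
    if n_genes < 7:
        raise ValueError("pathways need at least 7 genes")
    if n_states != tree.n_states:
        raise ValueError("n_states must match the tree")
    rng = np.random.default_rng(seed)

    n_motif = int(round(motif_fraction * n_profiles))
    n_private = n_profiles - n_motif
    if n_private > tree.n_clades:
        raise ValueError(
            f"{n_private} private profiles do not fit in {tree.n_clades} clades"
        )
    if n_motif > 0 and tree.n_clades < 3:
        raise ValueError("motif profiles need at least 3 clades")

    profiles: list[np.ndarray] = []
    for _ in range(n_profiles):
        for _attempt in range(10_000):
            cand = _sample_profile(rng, n_genes)
            if _min_cosine_distance(cand, profiles) >= min_profile_distance:
                profiles.append(cand)
                break
        else:
            raise RuntimeError("could not sample separable profiles; lower K or margin")
    prof_arr = np.vstack(profiles)
    # every pathway gene is strongly expressed in at least one profile
    # (mirrors real pathways, where each component appears in some profile);
    # otherwise that gene's q95 scale collapses to baseline noise downstream
    usage_w = usage_skew ** np.arange(n_profiles)
    for g in np.flatnonzero(prof_arr.max(axis=0) < 0.3):
        p = int(rng.choice(n_profiles, p=usage_w / usage_w.sum()))
        prof_arr[p, g] = rng.uniform(0.7, 1.0)

    class_truth = ["motif"] * n_motif + ["private"] * n_private
    private_ids = list(range(n_motif, n_profiles))
    private_clades = rng.choice(tree.n_clades, size=n_private, replace=False)
    private_clade = {p: int(c) for p, c in zip(private_ids, private_clades)}
    clade_of_private = {c: p for p, c in private_clade.items()}
    motif_ids = list(range(n_motif))

    motif_w = np.array([usage_skew**m for m in motif_ids])
    motif_w = motif_w / motif_w.sum() if motif_ids else motif_w
    assignment = np.full(n_states, OFF, dtype=int)
    n_off = int(round(off_fraction * n_states))
    off_states = rng.choice(n_states, size=n_off, replace=False)
    on_states = np.setdiff1d(np.arange(n_states), off_states)
    for s in on_states:
        c = tree.clade_id[s]
        if c in clade_of_private and (not motif_ids or rng.random() < 0.5):
            assignment[s] = clade_of_private[c]
        elif motif_ids:
            assignment[s] = motif_ids[int(rng.choice(len(motif_ids), p=motif_w))]
        # else: only private profiles exist and this clade has none → stays off

    _ensure_motif_spread(assignment, tree.clade_id, motif_ids, rng)
    for m in motif_ids:
        if len(set(tree.clade_id[assignment == m])) < 3:
            raise RuntimeError("motif spread repair failed; increase n_states")
    amplitude = rng.uniform(*amplitude_range, size=n_states)
    amplitude[assignment == OFF] = 1.0
    return PlantedProfileSet(
        prof_arr, class_truth, assignment, amplitude, private_clade,
        ambiguous=n_profiles == 1,
    )


def _ensure_motif_spread(
    assignment: np.ndarray,
    clade_id: np.ndarray,
    motif_ids: list[int],
    rng: np.random.Generator,
    min_clades: int = 3,
) -> None:
    """Reassign states so every motif spans at least ``min_clades`` clades."""
    for m in motif_ids:
        for _ in range(100):
            covered = set(clade_id[assignment == m])
            if len(covered) >= min_clades:
                break
            donors = np.flatnonzero(
                np.isin(assignment, motif_ids)
                & (assignment != m)
                & ~np.isin(clade_id, list(covered))
            )
            if donors.size == 0:
                raise ValueError("cannot spread motif over 3 clades; too few on states")
            assignment[donors[int(rng.integers(donors.size))]] = m


# ---------------------------------------------------------------------------
# count emission


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _gene_model(
    truth: SyntheticTruth, n_background: int
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic per-gene amplitudes and background loadings for a truth.

    Returns (gene_names, pathway_amplitudes, background_loadings, bias).
    Shared between dataset and trajectory emission so gene scales agree.
    """
    ng = truth.planted.n_genes
    d_lat = truth.tree.latent_coords.shape[1]
    rng = np.random.default_rng([truth.noise_params.seed, 7202])
    amp = rng.uniform(5.0, 15.0, size=ng)
    w = rng.standard_normal((n_background, d_lat)) / np.sqrt(d_lat)
    bias = rng.normal(0.5, 0.5, size=n_background)
    names = [f"PWG{i:03d}" for i in range(ng)] + [
        f"BG{j:04d}" for j in range(n_background)
    ]
    return names, amp, w, bias


def expected_state_expression(
    truth: SyntheticTruth,
    n_background: int = 300,
    off_baseline: float = 0.06,
) -> pd.DataFrame:
    """Noise-free expected expression (arbitrary units) per state and gene.

    Pathway genes follow the assigned planted profile times a per-gene
    amplitude; off states get heterogeneous low baselines in (0,
    ``off_baseline``) rather than one shared low profile, so they cannot
    form a coherent spurious cluster. Background genes are a softplus of a
    random linear map of the latent coordinates, so their *composition*
    carries the clade structure. Background totals are equalized across
    states so a state's pathway fraction depends only on its planted
    profile, not on its clade.
    """
    names, amp, w, bias = _gene_model(truth, n_background)
    planted, tree = truth.planted, truth.tree
    base_rng = np.random.default_rng([truth.noise_params.seed, 4181])
    scaled = base_rng.uniform(
        0.0, off_baseline, size=(tree.n_states, planted.n_genes)
    )
    on = planted.assignment != OFF
    scaled[on] = np.maximum(
        planted.profiles[planted.assignment[on]]
        * planted.amplitude[on, None],
        scaled[on],
    )
    pathway = scaled * amp[None, :]
    background = _softplus(tree.latent_coords @ w.T + bias[None, :])
    background *= (5.0 * n_background) / background.sum(axis=1, keepdims=True)
    values = np.hstack([pathway, background])
    index = [f"s{i:04d}" for i in range(tree.n_states)]
    return pd.DataFrame(values, index=index, columns=names)


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with mean mu, var mu + dispersion·mu²."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _state_meta_frame(truth: SyntheticTruth) -> pd.DataFrame:
    tree = truth.tree
    return pd.DataFrame(
        {
            "state": [f"s{i:04d}" for i in range(tree.n_states)],
            "clade": tree.clade_id,
            "organ": [f"organ{c}" for c in tree.clade_id],
            "cell_class": [f"class{c % 3}" for c in tree.clade_id],
            "profile_truth": truth.planted.assignment,
        }
    )


def emit_single_cell_datasets(
    truth: SyntheticTruth,
    n_datasets: int = 3,
    cells_per_state: int = 10,
    depth: float | None = None,
    n_background: int = 300,
    gene_dropout: float = 0.1,
    exact: bool = False,
) -> list[ad.AnnData]:
    """Emit raw count matrices for ``n_datasets`` pseudo-datasets.

    States are partitioned across datasets (each state appears in exactly
    one, as when atlases cover different tissues). Each dataset keeps all
    pathway genes but drops a random ``gene_dropout`` fraction of background
    genes, so gene sets overlap without being identical. Counts are
    negative-binomial around the state's expected expression scaled to the
    requested mean ``depth`` per cell; ``exact=True`` skips count noise and
    returns the expected values themselves (for noise-free oracles).
    """
    if depth is None:
        depth = truth.noise_params.depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([truth.noise_params.seed, 9311])
    expected = expected_state_expression(truth, n_background)
    probs = expected.to_numpy() / expected.to_numpy().sum(axis=1, keepdims=True)
    meta = _state_meta_frame(truth)

    n_states = truth.tree.n_states
    order = rng.permutation(n_states)
    out: list[ad.AnnData] = []
    for d in range(n_datasets):
        states = np.sort(order[d::n_datasets])
        n_bg_drop = int(round(gene_dropout * n_background))
        dropped = rng.choice(n_background, size=n_bg_drop, replace=False)
        keep = np.ones(expected.shape[1], dtype=bool)
        keep[truth.planted.n_genes + dropped] = False
        rows, obs_rows = [], []
        for s in states:
            mu = probs[s, keep] * depth
            for c in range(cells_per_state):
                rows.append(mu if exact else _nb_counts(rng, mu, truth.noise_params.dispersion))
                obs_rows.append({**meta.iloc[s].to_dict(), "dataset": f"syn{d}"})
        obs = pd.DataFrame(obs_rows)
        obs.index = [f"syn{d}_cell{i}" for i in range(len(obs))]
        x = np.vstack(rows).astype(np.float64)
        adata = ad.AnnData(
            x, obs=obs, var=pd.DataFrame(index=expected.columns[keep])
        )
        adata.uns["dataset_id"] = f"syn{d}"
        out.append(adata)
    return out


def emit_trajectory(
    truth: SyntheticTruth,
    n_stages: int = 7,
    dynamics: str = "stable",
    seed: int = 0,
    cells_per_stage: int = 40,
    n_background: int = 300,
    depth: float | None = None,
    switch_stage: int | None = None,
    exact: bool = False,
) -> TrajectorySim:
    """Emit an ordered staged trajectory with known profile dynamics.

    ``stable`` keeps one planted profile at full amplitude throughout;
    ``fade`` keeps the profile shape while its amplitude decays
    geometrically to near zero; ``switch`` expresses one profile up to
    ``switch_stage`` (default: middle stage) and the most distant other
    profile from then on, completing the change within one stage.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if dynamics not in ("stable", "fade", "switch"):
        raise ValueError(f"unknown dynamics {dynamics!r}")
    if depth is None:
        depth = truth.noise_params.depth
    planted = truth.planted
    rng = np.random.default_rng([truth.noise_params.seed, seed, 5507])

    # profile A: arbitrary deterministic pick; B: the profile farthest from A
    a = 0
    if dynamics == "switch":
        if planted.n_profiles < 2:
            raise ValueError("switch dynamics needs at least 2 planted profiles")
        d = squareform(pdist(planted.profiles, metric="cosine"))
        b = int(d[a].argmax())
        if switch_stage is None:
            switch_stage = n_stages // 2
        if not 1 <= switch_stage <= n_stages - 1:
            raise ValueError("switch_stage must be inside the trajectory")
    else:
        b, switch_stage = a, None

    profile_per_stage = np.full(n_stages, a)
    amplitude = np.ones(n_stages)
    if dynamics == "fade":
        amplitude = np.geomspace(1.0, 0.02, n_stages)
    elif dynamics == "switch":
        profile_per_stage[switch_stage:] = b

    names, amp, w, bias = _gene_model(truth, n_background)
    latent = truth.tree.centroids.mean(axis=0)
    background = 5.0 * _softplus(w @ latent + bias)
    rows, obs_rows = [], []
    for t in range(n_stages):
        pathway = amplitude[t] * planted.profiles[profile_per_stage[t]] * amp
        e = np.concatenate([np.maximum(pathway, 0.01), background])
        mu = e / e.sum() * depth
        for c in range(cells_per_stage):
            rows.append(mu if exact else _nb_counts(rng, mu, truth.noise_params.dispersion))
            obs_rows.append({"stage": t})
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"traj_cell{i}" for i in range(len(obs))]
    adata = ad.AnnData(
        np.vstack(rows).astype(np.float64), obs=obs, var=pd.DataFrame(index=names)
    )
    return TrajectorySim(adata, profile_per_stage, amplitude, dynamics, switch_stage)


def simulate_truth(
    n_states: int = 600,
    n_clades: int = 6,
    n_profiles: int = 6,
    n_genes: int = 11,
    motif_fraction: float = 0.5,
    separation: float = 10.0,
    d_lat: int = 10,
    noise_sd: float = 1.0,
    off_fraction: float = 0.15,
    depth: float = 3000.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Convenience constructor for a complete planted-truth atlas."""
    tree = generate_clade_tree(
        n_states, n_clades, separation, d_lat=d_lat, noise_sd=noise_sd, seed=seed
    )
    planted = plant_profiles(
        n_profiles,
        n_genes,
        n_states,
        tree,
        motif_fraction=motif_fraction,
        seed=seed + 1,
        off_fraction=off_fraction,
    )
    return SyntheticTruth(tree, planted, NoiseParams(depth, dispersion, seed))
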
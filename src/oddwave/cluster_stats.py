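"""Spatiotemporal cluster-based permutation test for paired ERP contrasts.

Given one difference wave (deviant minus standard) per participant, the test
computes a pointwise paired t map, thresholds it at a one-tailed cluster-
forming alpha (default p < 0.1), prunes suprathreshold samples that lack at
least ``minnbchan`` suprathreshold spatial neighbors at the same time point
(default 2), groups the survivors into spatiotemporally connected clusters
(spatial neighbors at the same sample, plus lag-1 temporal adjacency on the
same channel), scores each cluster by its mass (summed t), and evaluates the
most extreme observed mass against a sign-flip permutation distribution of
per-iteration extreme masses.  Monte-Carlo p-values use the (r + 1)/(n + 1)
convention, so p is never zero and the observed data count as one
permutation.

Sign flipping randomly negates each participant's whole difference wave,
which realizes exchangeability of the paired condition labels in a
within-participant design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .layout import ChannelLayout
from .immn import DifferenceWave

__all__ = [
    "TStatMap",
    "Cluster",
    "ClusterResult",
    "paired_t_map",
    "extract_clusters",
    "permutation_test",
]

CLUSTER_ALPHA = 0.1
MINNBCHAN = 2


@dataclass
class TStatMap:
    tvals: np.ndarray                 # (n_channels, n_samples); NaN outside window
    df: int
    times: np.ndarray                 # ms
    channel_names: list[str]
    window_ms: tuple[float, float]
    tail: str                         # "negative" | "positive" | "two_sided"

    def window_mask(self) -> np.ndarray:
        lo, hi = self.window_ms
        return (self.times >= lo) & (self.times <= hi)


@dataclass
class Cluster:
    members: list[tuple[str, float]]  # (channel name, time ms)
    member_indices: list[tuple[int, int]]
    mass: float
    sign: int
    monte_carlo_p: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray         # one extreme mass per permutation
    n_permutations: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def min_p(self) -> float | None:
        ps = [c.monte_carlo_p for c in self.clusters]
        return min(ps) if ps else None

    def to_json(self, path=None) -> str:
        payload = {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "config": self.config,
            "clusters": [
                {
                    "mass": c.mass,
                    "sign": c.sign,
                    "monte_carlo_p": c.monte_carlo_p,
                    "n_members": len(c.members),
                    "members": [[ch, t] for ch, t in c.members],
                }
                for c in self.clusters
            ],
            "null_max_mass": self.null_max_mass.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Pointwise statistic
# ---------------------------------------------------------------------------


def _stack(diffs) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    """Accept a list of DifferenceWave or an (n_subj, ch, samples) array."""
    if isinstance(diffs, np.ndarray):
        return diffs, None, None
    data = np.stack([d.data for d in diffs])
    times = diffs[0].times
    return data, times, None


def paired_t_map(
    diffs,
    window_ms: tuple[float, float] | None = None,
    times: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    tail: str = "negative",
) -> TStatMap:
    """Pointwise one-sample t map of per-participant difference waves.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n - 1 at every (channel, sample)
    inside ``window_ms``.  Zero-variance cells: 0/0 is defined as t = 0,
    c/0 as signed infinity; both raise a warning and infinite cells are
    excluded from clustering.
    """
    data, t_from_waves, _ = _stack(diffs)
    if times is None:
        times = t_from_waves
    if times is None:
        times = np.arange(data.shape[2], dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[1])]
    if window_ms is None:
        window_ms = (float(times[0]), float(times[-1]))

    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance cells; 0/0 set to t=0, "
            "c/0 to signed infinity (excluded from clustering)"
        )
        both_zero = zero_var & (mean == 0)
        tvals[both_zero] = 0.0
        tvals[zero_var & (mean > 0)] = np.inf
        tvals[zero_var & (mean < 0)] = -np.inf

    lo, hi = window_ms
    outside = ~((times >= lo) & (times <= hi))
    tvals[:, outside] = np.nan
    return TStatMap(tvals, n - 1, np.asarray(times, float), list(channel_names),
                    (float(lo), float(hi)), tail)


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------


def _threshold_mask(tvals: np.ndarray, df: int, cluster_alpha: float, tail: str) -> np.ndarray:
    tcrit = stats.t.ppf(1.0 - cluster_alpha, df)
    finite = np.isfinite(tvals)
    if tail == "negative":
        return finite & (tvals < -tcrit)
    if tail == "positive":
        return finite & (tvals > tcrit)
    if tail == "two_sided":
        tcrit2 = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
        return finite & (np.abs(tvals) > tcrit2)
    raise ValueError(f"unknown tail {tail!r}")


def _prune_mask(mask: np.ndarray, adjacency: np.ndarray, minnbchan: int) -> np.ndarray:
    """Keep a masked cell only if >= minnbchan of its spatial neighbors at the
    same sample are also masked.  Applied once, before clustering."""
    if minnbchan <= 0:
        return mask
    nb_count = adjacency.astype(int) @ mask
    return mask & (nb_count >= minnbchan)


def _cluster_labels(mask: np.ndarray, adjacency: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components over masked cells.

    Adjacency: spatial neighbors at the same sample plus lag-1 samples on the
    same channel (no wraparound).  Returns (labels over masked cells in
    row-major order, n_components).
    """
    n_ch, n_s = mask.shape
    nodes = np.flatnonzero(mask.ravel())
    if nodes.size == 0:
        return np.empty(0, dtype=int), 0
    id_of = -np.ones(n_ch * n_s, dtype=np.int64)
    id_of[nodes] = np.arange(nodes.size)

    rows, cols = [], []
    ei, ej = np.nonzero(np.triu(adjacency, 1))
    if ei.size:
        both = mask[ei, :] & mask[ej, :]
        e_idx, s_idx = np.nonzero(both)
        rows.append(id_of[ei[e_idx] * n_s + s_idx])
        cols.append(id_of[ej[e_idx] * n_s + s_idx])
    both_t = mask[:, :-1] & mask[:, 1:]
    c_idx, s_idx = np.nonzero(both_t)
    if c_idx.size:
        rows.append(id_of[c_idx * n_s + s_idx])
        cols.append(id_of[c_idx * n_s + s_idx + 1])

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        graph = csr_matrix((np.ones(r.size, dtype=np.int8), (r, c)),
                           shape=(nodes.size, nodes.size))
    else:
        graph = csr_matrix((nodes.size, nodes.size), dtype=np.int8)
    n_comp, labels = connected_components(graph, directed=False)
    return labels, n_comp


def _masses(tvals: np.ndarray, mask: np.ndarray, adjacency: np.ndarray,
             minnbchan: int) -> np.ndarray:
    """Cluster masses for one thresholded map (order arbitrary)."""
    pruned = _prune_mask(mask, adjacency, minnbchan)
    labels, n_comp = _cluster_labels(pruned, adjacency)
    if n_comp == 0:
        return np.empty(0)
    return np.bincount(labels, weights=tvals.ravel()[np.flatnonzero(pruned.ravel())],
                       minlength=n_comp)


def extract_clusters(
    tmap: TStatMap,
    cluster_alpha: float = CLUSTER_ALPHA,
    minnbchan: int = MINNBCHAN,
    layout: ChannelLayout | None = None,
    adjacency: np.ndarray | None = None,
) -> list[Cluster]:
    """Threshold, prune, and connect the t map into clusters with masses.

    ``adjacency`` (boolean channels x channels) may be given directly;
    otherwise it is derived from ``layout`` restricted to the map's channels.
    Clusters are returned sorted by descending |mass|.
    """
    if not 0.0 < cluster_alpha <= 0.5:
        raise ValueError("cluster_alpha must lie in (0, 0.5]")
    if adjacency is None:
        if layout is None:
            raise ValueError("need a layout or an adjacency matrix")
        adjacency = layout.adjacency_matrix(tmap.channel_names)
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (len(tmap.channel_names),) * 2:
        raise ValueError("adjacency does not match the t map's channels")

    tvals = np.nan_to_num(tmap.tvals, nan=0.0, posinf=0.0, neginf=0.0)
    finite_mask = _threshold_mask(tmap.tvals, tmap.df, cluster_alpha, tmap.tail)
    pruned = _prune_mask(finite_mask, adjacency, minnbchan)
    labels, n_comp = _cluster_labels(pruned, adjacency)
    if n_comp == 0:
        return []
    flat = np.flatnonzero(pruned.ravel())
    n_s = pruned.shape[1]
    clusters = []
    for k in range(n_comp):
        cells = flat[labels == k]
        ch_i, s_i = np.divmod(cells, n_s)
        mass = float(tvals.ravel()[cells].sum())
        clusters.append(
            Cluster(
                members=[(tmap.channel_names[c], float(tmap.times[s]))
                         for c, s in zip(ch_i, s_i)],
                member_indices=[(int(c), int(s)) for c, s in zip(ch_i, s_i)],
                mass=mass,
                sign=int(np.sign(mass)) or 1,
            )
        )
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return clusters


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def _extreme_mass(masses: np.ndarray, tail: str) -> float:
    """Per-iteration summary: the most extreme cluster mass (0 if none)."""
    if masses.size == 0:
        return 0.0
    if tail == "negative":
        return float(masses.min())
    if tail == "positive":
        return float(masses.max())
    return float(masses[np.argmax(np.abs(masses))])


def permutation_test(
    diffs,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = CLUSTER_ALPHA,
    minnbchan: int = MINNBCHAN,
    window_ms: tuple[float, float] | None = None,
    tail: str = "negative",
    layout: ChannelLayout | None = None,
    adjacency: np.ndarray | None = None,
    times: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test on a difference-wave stack.

    Each iteration independently negates each participant's difference wave,
    recomputes the t map, and records the most extreme cluster mass; a
    cluster's Monte-Carlo p is (r + 1)/(n_perm + 1) where r counts
    iterations at least as extreme as its observed mass.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    data, t_from_waves, _ = _stack(diffs)
    if times is None:
        times = t_from_waves
    if channel_names is None and not isinstance(diffs, np.ndarray) and layout is not None:
        channel_names = layout.scalp_channels if data.shape[1] == len(layout.scalp_channels) \
            else layout.channel_names

    tmap = paired_t_map(data, window_ms=window_ms, times=times,
                        channel_names=channel_names, tail=tail)
    if adjacency is None:
        if layout is None:
            raise ValueError("need a layout or an adjacency matrix")
        adjacency = layout.adjacency_matrix(tmap.channel_names)
    adjacency = np.asarray(adjacency, dtype=bool)

    observed = extract_clusters(tmap, cluster_alpha, minnbchan, adjacency=adjacency)

    # Precompute flattened, window-restricted data for fast permutation t maps:
    # under sign flips the per-cell sum of squares is invariant, so only the
    # mean changes per iteration.
    n, n_ch, n_s = data.shape
    wmask = tmap.window_mask()
    D = data[:, :, wmask].reshape(n, -1)
    ssq = np.einsum("ij,ij->j", D, D) / n
    df = n - 1
    tcrit = stats.t.ppf(1.0 - (cluster_alpha if tail != "two_sided" else cluster_alpha / 2), df)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_max = np.empty(n_perm)
    shape = (n_ch, int(wmask.sum()))
    for i in range(n_perm):
        m = signs[i] @ D / n
        var = (ssq - m * m) * (n / df)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0).reshape(shape)
        if tail == "negative":
            mask = t < -tcrit
        elif tail == "positive":
            mask = t > tcrit
        else:
            mask = np.abs(t) > tcrit
        null_max[i] = _extreme_mass(_masses(t, mask, adjacency, minnbchan), tail)

    for c in observed:
        if tail == "negative":
            r = int(np.sum(null_max <= c.mass))
        elif tail == "positive":
            r = int(np.sum(null_max >= c.mass))
        else:
            r = int(np.sum(np.abs(null_max) >= abs(c.mass)))
        c.monte_carlo_p = (r + 1) / (n_perm + 1)

    return ClusterResult(
        clusters=observed,
        null_max_mass=null_max,
        n_permutations=n_perm,
        seed=seed,
        config={
            "cluster_alpha": cluster_alpha,
            "minnbchan": minnbchan,
            "window_ms": list(tmap.window_ms),
            "tail": tail,
            "n_participants": n,
        },
    )
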
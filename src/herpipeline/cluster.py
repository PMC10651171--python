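"""Non-parametric spatiotemporal cluster-permutation test.

Unpaired group comparison of per-subject effect maps (channels x time):

1. Pointwise unpaired rank-sum Z (group A minus group B orientation).
2. Preliminary mask: pointwise two-sided p < alpha (0.05), split by Z sign.
3. Candidate clusters: per time sample, spatially connected components on
   the sensor neighbour graph; components with fewer than four distinct
   channels are dropped; surviving same-sign components at adjacent time
   samples are merged ("wrapped") when they share at least one channel,
   transitively.
4. Cluster statistic: max |Z| over the cluster's members.
5. Monte Carlo null: group labels are permuted (sizes preserved; exhaustive
   enumeration when the number of distinct partitions fits the budget,
   otherwise 10,000 uniform draws); each partition contributes the max |Z|
   over its own suprathreshold mask (0 when empty).  A cluster's Monte
   Carlo p is the plain proportion of partitions whose statistic is >= the
   cluster's (ties count as exceedances).

The min-channel and wrapping rules are not re-applied inside permutations:
the max-statistic null only needs each partition's suprathreshold maximum.
A config flag re-enables full per-permutation clustering for sensitivity
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from .core_io import NeighborGraph
from .epochs import EffectMap

__all__ = [
    "ZMap",
    "Cluster",
    "ClusterResult",
    "zmap_unpaired",
    "find_candidate_clusters",
    "permutation_test",
    "combined_cluster_effect",
]


@dataclass
class ZMap:
    """Pointwise rank-sum Z (positive = group A median larger) and p."""

    z: np.ndarray  # (n_channels, n_times)
    p: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape


@dataclass
class Cluster:
    members: list[tuple[int, int]]  # (channel, time-sample)
    sign: int                       # +1 or -1
    stat: float                     # max |Z| over members
    latency_ms: tuple[float, float]
    mc_p: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_channels(self) -> int:
        return len({c for c, _ in self.members})

    @property
    def channels(self) -> list[int]:
        return sorted({c for c, _ in self.members})


@dataclass
class ClusterResult:
    zmap: ZMap
    clusters: list[Cluster]
    perm_distribution: np.ndarray
    n_partitions: int
    seed: int
    exhaustive: bool = False
    combined_effects: dict = field(default_factory=dict)  # cluster idx -> per-subject values


# ---------------------------------------------------------------------------
# Vectorised rank-sum Z over maps
# ---------------------------------------------------------------------------

def _stack_maps(maps: list[EffectMap] | np.ndarray) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps
    return np.stack([m.map for m in maps])


def _rank_arrays(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks along the subject axis plus per-pixel tie correction term.

    ``data`` is (n_subjects, n_pixels); returns (ranks, tie_term) where
    tie_term[j] = sum over tie groups of (t^3 - t) at pixel j.
    """
    n, m = data.shape
    ranks = rankdata(data, axis=0)
    # tie term per pixel: count multiplicities via sorting; continuous
    # data has none, so only columns with ties take the slow path
    srt = np.sort(data, axis=0)
    tied_cols = np.nonzero((srt[1:] == srt[:-1]).any(axis=0))[0]
    tie_term = np.zeros(m)
    for j in tied_cols:
        new_grp = np.empty(n, dtype=bool)
        new_grp[0] = True
        new_grp[1:] = srt[1:, j] != srt[:-1, j]
        counts = np.diff(np.append(np.nonzero(new_grp)[0], n))
        tie_term[j] = float((counts.astype(float) ** 3 - counts).sum())
    return ranks, tie_term


def _z_from_rank_sums(w: np.ndarray, n_a: int, n_b: int, tie_term: np.ndarray) -> np.ndarray:
    n = n_a + n_b
    e_w = n_a * (n + 1) / 2.0
    var = n_a * n_b * (n + 1) / 12.0 - n_a * n_b * tie_term / (12.0 * n * (n - 1))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - e_w) / sd
    return np.where(sd > 0, z, 0.0)


def zmap_unpaired(
    maps_a: list[EffectMap] | np.ndarray, maps_b: list[EffectMap] | np.ndarray
) -> ZMap:
    """Pointwise unpaired rank-sum Z map, oriented A minus B."""
    a = _stack_maps(maps_a)
    b = _stack_maps(maps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"map dimensions differ: {a.shape[1:]} vs {b.shape[1:]}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    n_a = len(a)
    shape = a.shape[1:]
    data = np.concatenate([a, b]).reshape(len(a) + len(b), -1)
    ranks, tie_term = _rank_arrays(data)
    w = ranks[:n_a].sum(axis=0)
    z = _z_from_rank_sums(w, n_a, len(b), tie_term).reshape(shape)
    p = 2 * norm.sf(np.abs(z))
    return ZMap(z=z, p=p)


# ---------------------------------------------------------------------------
# Candidate clusters
# ---------------------------------------------------------------------------

def _components_at_time(channels: np.ndarray, graph: NeighborGraph) -> list[set[int]]:
    """Connected components of the suprathreshold channels at one sample."""
    chan_set = set(channels.tolist())
    seen: set[int] = set()
    comps = []
    for start in channels.tolist():
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            c = stack.pop()
            if c in comp:
                continue
            comp.add(c)
            stack.extend(graph.neighbors(c) & chan_set - comp)
        seen |= comp
        comps.append(comp)
    return comps


def find_candidate_clusters(
    zmap: ZMap,
    graph: NeighborGraph,
    alpha: float = 0.05,
    min_channels: int = 4,
    fs: float = 250.0,
) -> list[Cluster]:
    """Mask, per-sample spatial components, min-size rule, temporal wrapping."""
    clusters: list[Cluster] = []
    z_crit = norm.isf(alpha / 2)
    for sign in (+1, -1):
        mask = (sign * zmap.z) > z_crit
        # per-time-sample components surviving the min-channel rule
        per_t: dict[int, list[set[int]]] = {}
        for t in range(mask.shape[1]):
            chans = np.nonzero(mask[:, t])[0]
            if len(chans) == 0:
                continue
            comps = [c for c in _components_at_time(chans, graph)
                     if len(c) >= min_channels]
            if comps:
                per_t[t] = comps
        # wrap adjacent-sample components sharing >= 1 channel (transitive)
        nodes = [(t, i) for t in sorted(per_t) for i in range(len(per_t[t]))]
        parent = {nd: nd for nd in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[rx] = ry

        for t in sorted(per_t):
            if t + 1 not in per_t:
                continue
            for i, ci in enumerate(per_t[t]):
                for j, cj in enumerate(per_t[t + 1]):
                    if ci & cj:
                        union((t, i), (t + 1, j))

        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for nd in nodes:
            groups.setdefault(find(nd), []).append(nd)
        for members_nodes in groups.values():
            members = [(c, t) for (t, i) in members_nodes for c in per_t[t][i]]
            tmin = min(t for _, t in members)
            tmax = max(t for _, t in members)
            stat = float(np.abs([zmap.z[c, t] for c, t in members]).max())
            clusters.append(Cluster(
                members=sorted(members), sign=sign, stat=stat,
                latency_ms=(tmin * 1000.0 / fs, tmax * 1000.0 / fs),
            ))
    clusters.sort(key=lambda cl: -cl.stat)
    return clusters


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _partition_stats(
    data: np.ndarray,
    ranks: np.ndarray,
    tie_term: np.ndarray,
    n_a: int,
    picks: np.ndarray,
    z_crit: float,
) -> np.ndarray:
    """Max |Z| over the suprathreshold mask for each partition.

    ``picks`` is (n_partitions, n_a) subject indices forming group A.
    """
    n = data.shape[0]
    n_b = n - n_a
    sel = np.zeros((len(picks), n))
    rows = np.repeat(np.arange(len(picks)), n_a)
    sel[rows, picks.ravel()] = 1.0
    w = sel @ ranks  # (n_partitions, n_pixels)
    z = _z_from_rank_sums(w, n_a, n_b, tie_term[None, :])
    absz = np.abs(z)
    stat = absz.max(axis=1)
    return np.where(stat > z_crit, stat, 0.0)


def permutation_test(
    effects_a: list[EffectMap] | np.ndarray,
    effects_b: list[EffectMap] | np.ndarray,
    graph: NeighborGraph,
    n_partitions: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    min_channels: int = 4,
    fs: float = 250.0,
) -> ClusterResult:
    """Cluster-permutation test of group A vs group B effect maps.

    Observed clusters are referred to the permutation distribution of the
    max suprathreshold |Z|; each cluster's Monte Carlo p is the plain
    proportion of partitions at or above its statistic.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if n_partitions < 100:
        warnings.warn("fewer than 100 partitions gives a coarse Monte Carlo p",
                      RuntimeWarning)
    a = _stack_maps(effects_a)
    b = _stack_maps(effects_b)
    zmap = zmap_unpaired(a, b)
    clusters = find_candidate_clusters(zmap, graph, alpha, min_channels, fs)

    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    data = np.concatenate([a, b]).reshape(n, -1)
    ranks, tie_term = _rank_arrays(data)
    z_crit = float(norm.isf(alpha / 2))

    from math import comb

    exhaustive = comb(n, n_a) <= n_partitions
    if exhaustive:
        picks = np.array(list(combinations(range(n), n_a)), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        picks = np.empty((n_partitions, n_a), dtype=int)
        for i in range(n_partitions):
            picks[i] = rng.permutation(n)[:n_a]

    # chunk to bound memory on large pixel counts
    n_pix = data.shape[1]
    chunk = max(1, int(2e7 // max(n_pix, 1)))
    stats = np.empty(len(picks))
    for s in range(0, len(picks), chunk):
        stats[s:s + chunk] = _partition_stats(
            data, ranks, tie_term, n_a, picks[s:s + chunk], z_crit
        )

    for cl in clusters:
        cl.mc_p = float((stats >= cl.stat).sum() / len(stats))

    return ClusterResult(
        zmap=zmap, clusters=clusters, perm_distribution=stats,
        n_partitions=len(picks), seed=seed, exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# Combined clustered effect
# ---------------------------------------------------------------------------

def combined_cluster_effect(
    maps: list[EffectMap] | np.ndarray, cluster: Cluster
) -> np.ndarray:
    """Per-subject mean of the effect map over the cluster's member points."""
    if cluster.size == 0:
        raise ValueError("cluster has no members")
    stacked = _stack_maps(maps)
    ch = np.array([c for c, _ in cluster.members])
    tt = np.array([t for _, t in cluster.members])
    return stacked[:, ch, tt].mean(axis=1)


def combined_pair_effect(
    maps: list[EffectMap] | np.ndarray,
    positive: Cluster | None,
    negative: Cluster | None,
) -> np.ndarray:
    """Positive-cluster mean minus negative-cluster mean per subject.

    When a test yields clusters of both signs, the per-subject combined
    effect is the difference of the two means; with a single sign it is
    just that cluster's mean.
    """
    if positive is None and negative is None:
        raise ValueError("need at least one cluster")
    stacked = _stack_maps(maps)
    out = np.zeros(stacked.shape[0])
    if positive is not None:
        out = out + combined_cluster_effect(stacked, positive)
    if negative is not None:
        out = out - combined_cluster_effect(stacked, negative)
    return out
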
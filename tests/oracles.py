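"""Independent brute-force oracles.

Deliberately naive re-implementations (loops, exhaustive enumeration)
kept free of any code shared with the package, so they can vouch for the
vectorised implementations on tiny problems.
"""

from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata


def ranksum_z_naive(a, b):
    """Rank-sum Z via explicit pooled midranks, tie-corrected variance."""
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    ranks = rankdata(pooled)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    w = sum(ranks[:n_a])
    e_w = n_a * (n + 1) / 2
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t ** 3 - t for t in ties.values())
    var = n_a * n_b * (n + 1) / 12 - n_a * n_b * tie_term / (12 * n * (n - 1))
    if var <= 0:
        return 0.0
    return (w - e_w) / np.sqrt(var)


def ranksum_exact_p(a, b):
    """Exact two-sided p by enumerating every group assignment."""
    pooled = np.array(list(a) + list(b), dtype=float)
    n_a = len(a)
    obs = abs(ranksum_z_naive(a, b))
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        z = abs(ranksum_z_naive(pooled[sel], pooled[~sel]))
        total += 1
        if z >= obs - 1e-12:
            count += 1
    return count / total


def signed_rank_exact_p(values):
    """Exact two-sided p by enumerating all sign assignments."""
    v = np.array([x for x in values if x != 0], dtype=float)
    n = len(v)
    ranks = rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    e_w = n * (n + 1) / 4
    obs_dev = abs(w_obs - e_w)
    count = 0
    for signs in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if (signs >> i) & 1)
        if abs(w - e_w) >= obs_dev - 1e-12:
            count += 1
    return count / 2 ** n


def cluster_mc_p_naive(maps_a, maps_b, adjacency, alpha=0.05):
    """Exhaustive cluster-permutation Monte Carlo p, coded from scratch.

    Returns (clusters, mc_ps): observed clusters as (sign, members,
    max|Z|) built by full per-sample component search plus temporal
    wrapping, and the proportion of all label partitions whose
    max-suprathreshold |Z| meets each observed statistic.
    """
    z_crit = norm.isf(alpha / 2)
    n_a = len(maps_a)
    stacked = np.concatenate([maps_a, maps_b])
    n, n_ch, n_t = stacked.shape

    def zmat(idx_a):
        idx_b = [i for i in range(n) if i not in idx_a]
        out = np.zeros((n_ch, n_t))
        for c in range(n_ch):
            for t in range(n_t):
                out[c, t] = ranksum_z_naive(
                    stacked[list(idx_a), c, t], stacked[idx_b, c, t]
                )
        return out

    def clusters_of(z):
        found = []
        for sign in (1, -1):
            mask = sign * z > z_crit
            comps_per_t = {}
            for t in range(n_t):
                chans = set(np.nonzero(mask[:, t])[0].tolist())
                comps = []
                while chans:
                    seed_ch = chans.pop()
                    comp = {seed_ch}
                    grew = True
                    while grew:
                        grew = False
                        for c in list(chans):
                            if any(c in adjacency[m] for m in comp):
                                comp.add(c)
                                chans.discard(c)
                                grew = True
                    comps.append(comp)
                comps = [c for c in comps if len(c) >= 4]
                if comps:
                    comps_per_t[t] = comps
            # temporal wrapping by repeated merging
            pieces = [(t, frozenset(c)) for t in comps_per_t for c in comps_per_t[t]]
            merged = [{p} for p in pieces]
            changed = True
            while changed:
                changed = False
                for i in range(len(merged)):
                    for j in range(i + 1, len(merged)):
                        if any(
                            abs(t1 - t2) == 1 and (c1 & c2)
                            for (t1, c1) in merged[i]
                            for (t2, c2) in merged[j]
                        ):
                            merged[i] |= merged[j]
                            del merged[j]
                            changed = True
                            break
                    if changed:
                        break
            for group in merged:
                members = [(c, t) for (t, comp) in group for c in comp]
                stat = max(abs(z[c, t]) for c, t in members)
                found.append((sign, sorted(members), stat))
        return found

    obs_z = zmat(list(range(n_a)))
    obs_clusters = clusters_of(obs_z)

    perm_stats = []
    for idx in combinations(range(n), n_a):
        z = zmat(list(idx))
        supra = np.abs(z) > z_crit
        perm_stats.append(np.abs(z)[supra].max() if supra.any() else 0.0)
    perm_stats = np.array(perm_stats)

    mc_ps = [float((perm_stats >= stat).mean()) for (_, _, stat) in obs_clusters]
    return obs_clusters, mc_ps, perm_stats
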
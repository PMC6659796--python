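"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library code paths (and scipy/lifelines
shortcuts) they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def upgma_oracle(points: np.ndarray) -> list[tuple[int, int, float, int]]:
    """O(n^3) average-linkage agglomeration with lowest-index tie-breaking.

    Returns scipy-style merge rows (id_a, id_b, height, size) where original
    points are 0..n-1 and the cluster formed at step t gets id n + t.
    Inter-cluster distance is the mean over all pairwise point distances.
    """
    n = len(points)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    pdists = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = float(np.mean([pdists[i, j] for i in clusters[a] for j in clusters[b]]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d, len(clusters[next_id])))
        next_id += 1
    return merges


def mann_whitney_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Two-sided p is the probability, over all C(n, n_x) relabelings of the
    pooled data, of a U at least as far from its null mean as observed.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    mu = nx * ny / 2.0
    obs_dev = abs(u_stat(x, y) - mu)
    count = total = 0
    for idx in itertools.combinations(range(nx + ny), nx):
        mask = np.zeros(nx + ny, bool)
        mask[list(idx)] = True
        dev = abs(u_stat(pooled[mask], pooled[~mask]) - mu)
        count += dev >= obs_dev - 1e-12
        total += 1
    return count / total


def logrank_statistic(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> float:
    """Hand-computed two-group log-rank chi-square (O-E form)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group)
    g0 = np.unique(group)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (group == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d0 = ((times == t) & (events == 1) & (group == g0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def logrank_permutation_p(
    times: np.ndarray, events: np.ndarray, group: np.ndarray,
    n_perm: int = 2000, seed: int = 0,
) -> float:
    """Permutation-null p-value for the log-rank statistic."""
    rng = np.random.default_rng(seed)
    obs = logrank_statistic(times, events, group)
    group = np.asarray(group)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        hits += logrank_statistic(times, events, perm) >= obs - 1e-12
    return hits / n_perm


def km_hand_oracle() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A worked 6-subject product-limit example with mixed censoring.

    times {1, 2+, 3, 4, 5+, 6}: S steps 5/6 at t=1, 5/6 * 3/4 = 0.625 at
    t=3, 0.625 * 2/3 at t=4, and 0 at t=6 (last subject fails).
    """
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 0, 1, 1, 0, 1])
    expected = {1.0: 5 / 6, 3.0: 5 / 6 * 3 / 4, 4.0: 5 / 6 * 3 / 4 * 2 / 3, 6.0: 0.0}
    return times, events, expected


def piecewise_linear_root(conc: np.ndarray, viab: np.ndarray) -> float | None:
    """First root of (piecewise-linear interpolant of viability) - 50.

    Dense numeric bracketing on each segment; independent of the analytic
    bracketing formula it checks.
    """
    for i in range(len(conc) - 1):
        v0, v1 = viab[i] - 50.0, viab[i + 1] - 50.0
        if v0 == 0.0:
            return float(conc[i])
        if v0 > 0.0 > v1:
            # bisection on the linear segment
            lo, hi = conc[i], conc[i + 1]
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                vm = np.interp(mid, conc, viab) - 50.0
                if vm > 0:
                    lo = mid
                else:
                    hi = mid
            return float(0.5 * (lo + hi))
    if viab[-1] == 50.0:
        return float(conc[-1])
    return None
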
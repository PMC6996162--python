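"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the library code paths (and scipy shortcuts
where the point is independence): mid-ranks by scanning sorted positions,
monotone regression by naive pool-adjacent-violators, crossings by
adjacent-pair scan, and permutation nulls by vectorised rank shuffling.
"""

import numpy as np


def brute_force_midranks(pooled):
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def _tie_sum(pooled):
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    return sum(t**3 - t for t in counts.values())


def brute_force_h(groups):
    sizes = [len(g) for g in groups]
    pooled = [v for g in groups for v in g]
    ranks = brute_force_midranks(pooled)
    n = len(pooled)
    idx, term = 0, 0.0
    for size in sizes:
        mean_rank = sum(ranks[idx : idx + size]) / size
        term += size * mean_rank**2
        idx += size
    h = 12.0 / (n * (n + 1)) * term - 3 * (n + 1)
    correction = 1.0 - _tie_sum(pooled) / (n**3 - n)
    return 0.0 if correction <= 0 else h / correction


def brute_force_q(groups, control_index):
    sizes = [len(g) for g in groups]
    pooled = [v for g in groups for v in g]
    ranks = brute_force_midranks(pooled)
    n = len(pooled)
    means, idx = [], 0
    for size in sizes:
        means.append(sum(ranks[idx : idx + size]) / size)
        idx += size
    var = n * (n + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (n - 1))
    out = []
    for i in range(len(groups)):
        if i == control_index:
            continue
        se = (var * (1.0 / sizes[i] + 1.0 / sizes[control_index])) ** 0.5
        out.append(abs(means[i] - means[control_index]) / se if se > 0 else 0.0)
    return out


def permutation_p_of_h(groups, h_observed, n_perm, rng):
    """Sampled permutation p-value of the Kruskal-Wallis H statistic.

    Ranks are invariant under permutation, so shuffle the rank vector and
    recompute H vectorised over permutations.
    """
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = np.array(brute_force_midranks(pooled.tolist()))
    n = pooled.size
    correction = 1.0 - _tie_sum(pooled.tolist()) / (n**3 - n)
    perms = np.tile(ranks, (n_perm, 1))
    rng.permuted(perms, axis=1, out=perms)
    bounds = np.cumsum(sizes)[:-1]
    h_perm = np.zeros(n_perm)
    start = 0
    for size, stop in zip(sizes, list(bounds) + [n]):
        means = perms[:, start:stop].mean(axis=1)
        h_perm += size * means**2
        start = stop
    h_perm = (12.0 / (n * (n + 1)) * h_perm - 3 * (n + 1)) / correction
    return float(np.mean(h_perm >= h_observed - 1e-12))


def pava_crossing(levels, amps, criterion):
    """Naive non-increasing PAVA followed by an adjacent-pair scan for the
    first downward crossing of the criterion.  Returns (value, censor)."""
    fitted = [float(a) for a in amps]
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(fitted) - 1:
            if fitted[i] < fitted[i + 1] - 1e-15:
                avg = (fitted[i] + fitted[i + 1]) / 2.0
                fitted[i] = fitted[i + 1] = avg
                j = i
                while j > 0 and fitted[j - 1] < fitted[j] - 1e-15:
                    avg = float(np.mean(fitted[j - 1 : i + 2]))
                    for k in range(j - 1, i + 2):
                        fitted[k] = avg
                    j -= 1
                changed = True
            i += 1
    if fitted[0] < criterion:
        return None, "below"
    for i in range(1, len(fitted)):
        if fitted[i] < criterion:
            y0, y1 = fitted[i - 1], fitted[i]
            x0, x1 = levels[i - 1], levels[i]
            return x0 + (y0 - criterion) / (y0 - y1) * (x1 - x0), None
    return None, "above"
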
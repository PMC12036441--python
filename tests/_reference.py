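"""Independent brute-force reference implementations used as test oracles.

Deliberately naive (queue-based flood fill, direct formula evaluation,
textbook step-up enumeration) and kept free of any lucidmap internals so
they exercise genuinely different code paths than the package.
"""

from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int):
    """All 3D integer offsets for a 6/18/26 neighborhood."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                n_nonzero = sum(1 for d in (dx, dy, dz) if d != 0)
                if n_nonzero == 0:
                    continue
                if connectivity == 6 and n_nonzero > 1:
                    continue
                if connectivity == 18 and n_nonzero > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def bfs_components(binary: np.ndarray, connectivity: int):
    """Connected components by explicit breadth-first flood fill.

    Returns a list of frozensets of voxel index tuples.
    """
    binary = np.asarray(binary, dtype=bool)
    offs = neighbor_offsets(connectivity)
    seen = np.zeros(binary.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = []
        while queue:
            x, y, z = queue.popleft()
            comp.append((x, y, z))
            for dx, dy, dz in offs:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < binary.shape[i] for i in range(3)) \
                        and binary[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        comps.append(frozenset(comp))
    return comps


def signed_cluster_sets(data: np.ndarray, theta: float, connectivity: int,
                        min_size: int = 0):
    """Sign-split suprathreshold components as a set of frozensets."""
    comps = []
    for supra in (data >= theta, data <= -theta):
        comps.extend(bfs_components(supra, connectivity))
    return {c for c in comps if len(c) >= min_size}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() and not b.any():
        return 1.0
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Direct evaluation of the sample-correlation formula."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    mx, my = x.mean(), y.mean()
    num = np.sum((x - mx) * (y - my))
    den = np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    return float(num / den)


def bh_stepup(pvals: np.ndarray, q: float) -> np.ndarray:
    """Textbook Benjamini-Hochberg: reject p <= p(i*) where
    i* = max{i : p(i) <= i*q/m} (1-based ranks)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    istar = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= i * q / m:
            istar = i
    reject = np.zeros(m, dtype=bool)
    if istar > 0:
        reject = p <= sorted_p[istar - 1]
    return reject


def max_cluster_sizes_null(shape, n_iter, seed, theta, connectivity):
    """Plain re-implementation of the unsmoothed null cluster loop."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        noise = rng.standard_normal(shape)
        field = (noise - noise.mean()) / noise.std()
        best = 0
        for comp in signed_cluster_sets(field, theta, connectivity):
            best = max(best, len(comp))
        out.append(best)
    return np.asarray(out)
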
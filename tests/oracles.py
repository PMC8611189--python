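"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a direct transcription of the defining formula or
an exhaustive enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_neighbor_sets(mask: np.ndarray) -> dict[int, set[int]]:
    """26-neighborhood by scanning every pair of in-mask cells."""
    coords = [tuple(c) for c in np.argwhere(mask)]
    index = {c: k for k, c in enumerate(coords)}
    nbrs: dict[int, set[int]] = {k: set() for k in index.values()}
    for a, b in combinations(coords, 2):
        if all(abs(x - y) <= 1 for x, y in zip(a, b)):
            nbrs[index[a]].add(index[b])
            nbrs[index[b]].add(index[a])
    return nbrs


def closure_components(voxels: set[int], neighbor_sets: dict[int, set[int]]):
    """Connected components by repeated transitive closure."""
    remaining = set(voxels)
    comps = []
    while remaining:
        comp = {min(remaining)}
        while True:
            grown = set(comp)
            for v in comp:
                grown |= neighbor_sets.get(v, set()) & remaining
            if grown == comp:
                break
            comp = grown
        comps.append(frozenset(comp))
        remaining -= comp
    return set(comps)


def brute_modularity(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Literal double sum of the resolution-parametrized modularity."""
    n = W.shape[0]
    k = [sum(W[i][j] for j in range(n)) for i in range(n)]
    two_m = sum(k)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i][j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items: list):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[head] + part[k]] + part[k + 1 :]
        yield [[head]] + part


def max_modularity_partition(W: np.ndarray, gamma: float):
    """Exhaustive maximum-Q partition (tiny graphs only)."""
    n = W.shape[0]
    best_q, best = -np.inf, None
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        q = brute_modularity(W, labels, gamma)
        if q > best_q:
            best_q, best = q, [sorted(b) for b in part]
    return best_q, best


def entropy_nmi(a: np.ndarray, b: np.ndarray) -> float:
    """NMI from first principles: plug-in entropies, arithmetic-mean norm."""
    n = len(a)

    def counts(x):
        out: dict = {}
        for v in x:
            out[v] = out.get(v, 0) + 1
        return out

    ca, cb = counts(a), counts(b)
    cab = counts(list(zip(a, b)))
    ha = -sum(c / n * math.log(c / n) for c in ca.values())
    hb = -sum(c / n * math.log(c / n) for c in cb.values())
    mi = 0.0
    for (va, vb), c in cab.items():
        pij = c / n
        mi += pij * math.log(pij / (ca[va] / n * cb[vb] / n))
    if ha == 0 and hb == 0:
        return 1.0
    denom = (ha + hb) / 2
    return mi / denom if denom > 0 else 0.0


def pairwise_pearson(X: np.ndarray) -> np.ndarray:
    """Per-pair textbook Pearson correlation of columns of X."""
    T, V = X.shape
    R = np.eye(V)
    for i in range(V):
        for j in range(i + 1, V):
            xi, xj = X[:, i], X[:, j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = math.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            R[i, j] = R[j, i] = num / den
    return R


def similarity_loop(u_row, v_row, sizes, skip) -> float:
    """Straight-loop size-weighted RMS profile distance."""
    num = den = 0.0
    for k in range(len(sizes)):
        if k in skip:
            continue
        num += sizes[k] * (u_row[k] - v_row[k]) ** 2
        den += sizes[k]
    return math.sqrt(num / den)


def homogeneity_loops(labels: np.ndarray, X: np.ndarray):
    """Straight-loop intra/inter CC summaries per module."""
    ids = sorted(set(labels.tolist()))
    means = {m: X[:, labels == m].mean(axis=1) for m in ids}
    out = {}
    for m in ids:
        vox = np.flatnonzero(labels == m)
        if len(vox) >= 2:
            R = pairwise_pearson(X[:, vox])
            vals = [R[i, j] for i in range(len(vox)) for j in range(len(vox)) if i != j]
            intra = sum(vals) / len(vals)
        else:
            intra = float("nan")
        inters = [
            pairwise_pearson(np.column_stack([means[m], means[o]]))[0, 1]
            for o in ids
            if o != m
        ]
        out[m] = (intra, sum(inters) / len(inters))
    return out
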
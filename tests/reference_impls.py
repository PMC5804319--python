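"""Independent reference implementations used only as test oracles.

These are deliberately written with dense numpy and naive loops, sharing no
code with the package, so they can arbitrate the sparse MCL and the Ward
linkage used by the pipeline.
"""

from __future__ import annotations

import numpy as np


def reference_mcl_partition(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    inflation: float,
    eps: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[frozenset[str]]:
    """Dense, loop-based MCL: same algorithm contract, independent code.

    Self-loop per node = max incident weight (1 if isolated); columns
    normalized; iterate square -> entrywise power -> normalize -> prune
    (keeping each column's max) -> normalize; clusters = components of the
    converged support.
    """
    idx = {n: i for i, n in enumerate(sorted(nodes))}
    n = len(idx)
    m = np.zeros((n, n))
    for a, b, w in edges:
        i, j = idx[a], idx[b]
        m[i, j] = max(m[i, j], w)
        m[j, i] = max(m[j, i], w)
    for i in range(n):
        incident = m[i].max()
        m[i, i] = incident if incident > 0 else 1.0
    m = m / m.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        nxt = m @ m
        nxt = nxt**inflation
        nxt = nxt / nxt.sum(axis=0, keepdims=True)
        for j in range(n):
            col = nxt[:, j]
            mx = col.argmax()
            col[(col < eps)] = 0.0
            if col.sum() == 0:
                col[mx] = 1.0
            nxt[:, j] = col
        colsum = nxt.sum(axis=0, keepdims=True)
        # restore the pruned-away max entry exactly as kept
        nxt = nxt / colsum
        if np.abs(nxt - m).max() < tol:
            m = nxt
            break
        m = nxt

    support = (m + m.T) > 0
    names = sorted(idx, key=idx.get)
    seen: set[int] = set()
    parts: list[frozenset[str]] = []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(np.nonzero(support[v])[0].tolist())
        seen |= comp
        parts.append(frozenset(names[v] for v in comp))
    return parts


def naive_ward_heights(x: np.ndarray) -> np.ndarray:
    """Merge heights of Ward linkage by the Lance–Williams recurrence.

    Greedy nearest-pair agglomeration on squared Euclidean distances,
    returning the sorted vector of merge heights (the scale scipy reports).
    """
    n = x.shape[0]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = float(((x[i] - x[j]) ** 2).sum())
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                if best is None or d2[i, j] < best[0]:
                    best = (d2[i, j], i, j)
        dij, i, j = best
        heights.append(np.sqrt(dij))
        ni, nj = sizes[i], sizes[j]
        for k in sorted(active - {i, j}):
            nk = sizes[k]
            d2_new = (
                (ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * dij
            ) / (ni + nj + nk)
            d2[i, k] = d2[k, i] = d2_new
        sizes[i] = ni + nj
        active.remove(j)
    return np.sort(np.array(heights))
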
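"""Independent brute-force oracles used by the tests.

Everything here is deliberately written by direct enumeration (python loops,
exhaustive subsets, pair counting) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


def _in(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def oracle_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts over the 13 offsets by pairwise enumeration."""
    glcm = np.zeros((n_levels, n_levels), dtype=int)
    shape = levels.shape
    for v in np.argwhere(mask):
        for d in DIRECTIONS_13:
            w = tuple(v + d)
            if _in(shape, w) and mask[w]:
                i = levels[tuple(v)] - 1
                j = levels[w] - 1
                glcm[i, j] += 1
                glcm[j, i] += 1
    return glcm


def oracle_glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run counts per (level, length) by walking every maximal run in 13 directions."""
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    for d in DIRECTIONS_13:
        for v in np.argwhere(mask):
            prev = tuple(v - d)
            lvl = levels[tuple(v)]
            if _in(shape, prev) and mask[prev] and levels[prev] == lvl:
                continue  # not a run start
            length = 0
            w = tuple(v)
            while _in(shape, w) and mask[w] and levels[w] == lvl:
                length += 1
                w = tuple(np.array(w) + d)
            runs[(lvl, length)] = runs.get((lvl, length), 0) + 1
    max_len = max(l for _, l in runs)
    out = np.zeros((n_levels, max_len), dtype=int)
    for (lvl, length), c in runs.items():
        out[lvl - 1, length - 1] = c
    return out


def oracle_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts by flood-fill (BFS, 26-connectivity) per gray level."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for v in map(tuple, np.argwhere(mask)):
        if seen[v]:
            continue
        lvl = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = tuple(np.array(u) + d)
                if _in(shape, w) and mask[w] and not seen[w] and levels[w] == lvl:
                    seen[w] = True
                    stack.append(w)
        zones[(lvl, size)] = zones.get((lvl, size), 0) + 1
    max_size = max(s for _, s in zones)
    out = np.zeros((n_levels, max_size), dtype=int)
    for (lvl, size), c in zones.items():
        out[lvl - 1, size - 1] += c
    return out


def oracle_ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level (n_i, s_i) with edge-corrected 26-neighbourhood means."""
    shape = levels.shape
    n_i = np.zeros(n_levels, dtype=int)
    s_i = np.zeros(n_levels, dtype=float)
    for v in map(tuple, np.argwhere(mask)):
        nb = [
            levels[tuple(np.array(v) + d)]
            for d in NEIGHBORS_26
            if _in(shape, tuple(np.array(v) + d)) and mask[tuple(np.array(v) + d)]
        ]
        if not nb:
            continue
        lvl = levels[v]
        n_i[lvl - 1] += 1
        s_i[lvl - 1] += abs(lvl - float(np.mean(nb)))
    return n_i, s_i


def oracle_best_subset(F: np.ndarray, f: np.ndarray, size: int):
    """Exhaustive search for the column subset minimizing the LS residual."""
    best = None
    best_res = np.inf
    for subset in itertools.combinations(range(F.shape[1]), size):
        coef, *_ = np.linalg.lstsq(F[:, list(subset)], f, rcond=None)
        res = float(np.linalg.norm(f - F[:, list(subset)] @ coef))
        if res < best_res - 1e-12:
            best_res = res
            best = subset
    return set(best), best_res


def oracle_auc_pair_counting(scores, labels) -> float:
    """Mann-Whitney U / (n1*n0) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_nearest_subspace(X_train, y_train, X_test, max_dim=None):
    """Class-restricted least-squares (nearest subspace) classification."""
    preds = []
    classes = np.unique(y_train)
    for f in X_test:
        best_cls, best_res = None, np.inf
        for cls in classes:
            A = X_train[y_train == cls].T
            coef, *_ = np.linalg.lstsq(A, f, rcond=None)
            res = float(np.linalg.norm(f - A @ coef))
            if res < best_res:
                best_res, best_cls = res, cls
        preds.append(best_cls)
    return np.asarray(preds)
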
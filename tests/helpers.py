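"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: flood fill by
explicit stack walking, Wilcoxon by full enumeration of rank assignments,
Fisher by hypergeometric table enumeration, local thickness by direct
sphere search, Otsu by exhaustive between-class-variance scan.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of a small 2D binary image, by stack walking."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    rows, cols = binary.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if binary[r0, c0] and not seen[r0, c0]:
                comp = set()
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < rows
                                and 0 <= cc < cols
                                and binary[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-tailed rank-sum P by enumerating all C(n1+n2, n1) assignments.

    P = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) under the uniform
    permutation null (untied data).
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(1, n1 + n2 + 1), n1):
        us.append(sum(comb) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def fisher_enumeration(table) -> float:
    """Two-sided Fisher P by summing hypergeometric table probabilities."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs * (1.0 + 1e-7):
            total += pk
    return min(1.0, total)


def local_thickness_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Direct largest-containing-sphere search on a small 3D mask.

    th(x) = 2 * max over centers c with |x - c| <= dt(c) of dt(c), with dt
    the Euclidean distance to the nearest background voxel center.
    """
    from scipy import ndimage as ndi

    mask = np.asarray(mask, dtype=bool)
    dt = ndi.distance_transform_edt(mask)
    coords = np.argwhere(mask)
    th = np.zeros(mask.shape)
    for c in coords:
        r = dt[tuple(c)]
        if r <= 0:
            continue
        d2 = np.sum((coords - c) ** 2, axis=1)
        covered = coords[d2 <= r * r + 1e-9]
        vals = th[tuple(covered.T)]
        np.maximum.at(th, tuple(covered.T), 2.0 * r)
    return th


def otsu_scan(values: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold by exhaustive scan."""
    values = np.sort(np.asarray(values, dtype=float))
    best_t, best_var = values[0], -1.0
    candidates = (values[1:] + values[:-1]) / 2.0
    for t in np.unique(candidates):
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)
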
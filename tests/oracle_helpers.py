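"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: BH by sorted
enumeration, shortest paths by Floyd-Warshall triple loops, clustering by
explicit triangle enumeration, transfer matrices by hand-written 2x2
complex inversion.
"""

from __future__ import annotations

import math

import numpy as np


def bh_mask_bruteforce(p, q):
    """Benjamini-Hochberg step-up over the flat p-vector, by enumeration."""
    p = np.asarray(p, dtype=float).ravel()
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def floyd_warshall(w):
    """All-pairs shortest paths on edge lengths 1/w (symmetric input)."""
    n = w.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def graph_metrics_bruteforce(w):
    """C, L, Ge, Le of a symmetric weighted graph by explicit enumeration."""
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    # clustering: geometric-mean triangle intensity over ordered neighbour pairs
    C_nodes = []
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            C_nodes.append(0.0)
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        C_nodes.append(s / (k * (k - 1)))
    C = float(np.mean(C_nodes))

    d = floyd_warshall(w)
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    finite = [d[i, j] for i, j in off if math.isfinite(d[i, j])]
    L = float(np.mean(finite)) if finite else math.inf
    Ge = float(np.mean([1.0 / d[i, j] if math.isfinite(d[i, j]) and d[i, j] > 0
                        else 0.0 for i, j in off])) if off else 0.0

    Le_nodes = []
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            Le_nodes.append(0.0)
            continue
        sub = w[np.ix_(nb, nb)]
        dsub = floyd_warshall(sub)
        m = len(nb)
        pairs = [(a, b) for a in range(m) for b in range(m) if a != b]
        Le_nodes.append(float(np.mean(
            [1.0 / dsub[a, b] if math.isfinite(dsub[a, b]) and dsub[a, b] > 0
             else 0.0 for a, b in pairs])))
    Le = float(np.mean(Le_nodes))
    return C, L, Ge, Le


def inv2x2_complex(M):
    """Hand-written 2x2 complex matrix inverse."""
    a, b = M[0, 0], M[0, 1]
    c, d = M[1, 0], M[1, 1]
    det = a * d - b * c
    return np.array([[d, -b], [-c, a]], dtype=complex) / det


def simulate_var(A, n_samples, noise_sd=1.0, rng=None):
    """Direct VAR(p) simulation for ground-truth recovery tests."""
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    rng = rng if rng is not None else np.random.default_rng()
    y = np.zeros((n, n_samples))
    e = rng.standard_normal((n, n_samples)) * noise_sd
    for t in range(n_samples):
        acc = e[:, t].copy()
        for k in range(1, p + 1):
            if t - k >= 0:
                acc += A[k - 1] @ y[:, t - k]
        y[:, t] = acc
    return y
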
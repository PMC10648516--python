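"""Independent brute-force oracles used to cross-check the vectorized
implementations. Everything here is deliberately written as plain loops
over node pairs and dict lookups, sharing no code with netseg."""

from __future__ import annotations

import numpy as np


def brute_global_segregation(values, labels, types):
    """Pooled (mean within - mean between) / mean within over node pairs of
    assigned systems."""
    n = len(labels)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if types[labels[i]] == "unassigned" or types[labels[j]] == "unassigned":
                continue
            if labels[i] == labels[j]:
                within.append(values[i][j])
            else:
                between.append(values[i][j])
    mw = sum(within) / len(within)
    mb = sum(between) / len(between)
    return (mw - mb) / mw


def brute_per_system(values, labels, types):
    """Ws and Bs per assigned system (>= 2 nodes for Ws)."""
    n = len(labels)
    systems = []
    for lab in labels:
        if lab not in systems and types[lab] != "unassigned":
            systems.append(lab)
    ws, bs = {}, {}
    for s in systems:
        w_vals, b_vals = [], []
        for i in range(n):
            if labels[i] != s:
                continue
            for j in range(n):
                if i == j or types[labels[j]] == "unassigned":
                    continue
                if labels[j] == s:
                    if j > i:
                        w_vals.append(values[i][j])
                else:
                    b_vals.append(values[i][j])
        if w_vals:
            ws[s] = sum(w_vals) / len(w_vals)
        if b_vals:
            bs[s] = sum(b_vals) / len(b_vals)
    return ws, bs


def brute_type_segregation(values, labels, types, system_type):
    """Mean-of-means segregation for systems of one type."""
    ws, bs = brute_per_system(values, labels, types)
    w_list = [ws[s] for s in ws if types[s] == system_type]
    b_list = [bs[s] for s in ws if types[s] == system_type]
    gw = sum(w_list) / len(w_list)
    gb = sum(b_list) / len(b_list)
    return (gw - gb) / gw


def brute_mean_interactions(values, labels, types):
    """Grand means of Ws and Bs over all assigned systems."""
    ws, bs = brute_per_system(values, labels, types)
    w_list = [ws[s] for s in ws]
    b_list = [bs[s] for s in ws if s in bs]
    return sum(w_list) / len(w_list), sum(b_list) / len(b_list)


def brute_block_means(values, labels):
    """Dict of (system_a, system_b) -> mean over exactly that block's pairs."""
    n = len(labels)
    sums, counts = {}, {}
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((labels[i], labels[j])))
            sums[key] = sums.get(key, 0.0) + values[i][j]
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def normal_equations_beta(X, y):
    """OLS coefficients by explicitly solving the normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
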
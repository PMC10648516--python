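"""Brain system segregation and block-level summaries.

Global segregation pools *node pairs* across all assigned systems:

    segregation = (Zw - Zb) / Zw

where ``Zw`` is the mean Fisher-z connectivity over the W within-system
node pairs and ``Zb`` the mean over the B between-system node pairs
(W + B = N(N-1)/2 for N assigned nodes). A system disconnected from all
others reaches the maximum of 1; a uniform matrix gives 0.

System-type segregation (association vs sensory-motor) instead uses a
mean-of-means: for each system S of the requested type, ``Ws`` is the mean
over pairs inside S and ``Bs`` the mean over pairs from S to every other
assigned system (of either type); the statistic is
``(mean_S Ws - mean_S Bs) / mean_S Ws``. The two readings coincide for
equal-sized systems with block-constant connectivity but differ in general,
so they are deliberately distinct code paths.

Systems typed ``unassigned`` are excluded from every pool. Negative values
are assumed to have been zeroed upstream (see :mod:`netseg.netbuild`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedSegregationError
from .netbuild import ConnectivityMatrix
from .partition import ASSOCIATION, SENSORY_MOTOR, SystemPartition


@dataclass
class SegregationResult:
    """Global and system-type segregation of one connectivity matrix."""

    global_segregation: float
    mean_within: float              # pooled mean within-system z
    mean_between: float             # pooled mean between-system z
    n_within_pairs: int
    n_between_pairs: int
    assoc_segregation: float | None
    sensorimotor_segregation: float | None
    per_system_within: dict[str, float]   # Ws: mean z inside each system
    per_system_between: dict[str, float]  # Bs: mean z from system to all others


@dataclass
class BlockMatrix:
    """System x system matrix of block-mean connectivity.

    Diagonal entries are within-system block means; off-diagonal entries are
    between-system block means. A within block of a 1-node system is
    undefined and carried as NaN.
    """

    systems: tuple[str, ...]
    block_means: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.block_means, index=list(self.systems),
                            columns=list(self.systems))

    def to_long(self) -> pd.DataFrame:
        """Long format with one row per unique block (i <= j)."""
        rows = []
        for i, a in enumerate(self.systems):
            for j in range(i, len(self.systems)):
                rows.append((a, self.systems[j], self.block_means[i, j]))
        return pd.DataFrame(rows, columns=["system_a", "system_b", "mean_z"])


def _check_alignment(m: ConnectivityMatrix, p: SystemPartition) -> None:
    if m.node_ids != p.node_ids:
        raise FormatError("matrix node_ids do not match partition node_ids")


def _pair_sums(m: ConnectivityMatrix, p: SystemPartition):
    """Per-system-pair sums and counts over unique node pairs (assigned
    systems only). Returns (systems, sums SxS, counts SxS)."""
    systems = p.systems(assigned_only=True)
    idx = {s: i for i, s in enumerate(systems)}
    labels = np.asarray(
        [idx.get(s, -1) for s in p.system_of_node], dtype=int
    )
    keep = labels >= 0
    v = m.values[np.ix_(keep, keep)]
    lab = labels[keep]
    S = len(systems)
    one_hot = np.zeros((lab.size, S))
    one_hot[np.arange(lab.size), lab] = 1.0
    # sums over ordered node pairs, then fold to unordered
    total = one_hot.T @ v @ one_hot          # includes diagonal (which is 0)
    counts_ordered = np.outer(
        np.bincount(lab, minlength=S), np.bincount(lab, minlength=S)
    ).astype(float)
    np.fill_diagonal(
        counts_ordered,
        [c * (c - 1) for c in np.bincount(lab, minlength=S)],
    )
    sums = np.where(np.eye(S, dtype=bool), total / 2.0, total)
    counts = np.where(np.eye(S, dtype=bool), counts_ordered / 2.0, counts_ordered)
    return systems, sums, counts


def system_segregation(m: ConnectivityMatrix, p: SystemPartition) -> SegregationResult:
    """Global (node-pair pooled) segregation plus system-type variants."""
    _check_alignment(m, p)
    systems, sums, counts = _pair_sums(m, p)
    S = len(systems)
    diag = np.eye(S, dtype=bool)
    upper = np.triu(np.ones((S, S), dtype=bool), k=1)

    n_within = counts[diag].sum()
    n_between = counts[upper].sum()
    if n_within < 1 or n_between < 1:
        raise FormatError("need >= 1 within pair and >= 1 between pair")
    mean_w = sums[diag].sum() / n_within
    mean_b = sums[upper].sum() / n_between
    if mean_w == 0.0:
        raise UndefinedSegregationError("pooled mean within-system z is zero")
    global_seg = (mean_w - mean_b) / mean_w

    per_within: dict[str, float] = {}
    per_between: dict[str, float] = {}
    for i, s in enumerate(systems):
        if counts[i, i] > 0:
            per_within[s] = float(sums[i, i] / counts[i, i])
        off = ~diag[i]
        n_off = counts[i, off].sum()
        if n_off > 0:
            per_between[s] = float(sums[i, off].sum() / n_off)

    def _type_seg(stype: str) -> float | None:
        try:
            return system_type_segregation(m, p, stype, _precomputed=(systems, sums, counts))
        except (FormatError, UndefinedSegregationError):
            return None

    return SegregationResult(
        global_segregation=float(global_seg),
        mean_within=float(mean_w),
        mean_between=float(mean_b),
        n_within_pairs=int(n_within),
        n_between_pairs=int(n_between),
        assoc_segregation=_type_seg(ASSOCIATION),
        sensorimotor_segregation=_type_seg(SENSORY_MOTOR),
        per_system_within=per_within,
        per_system_between=per_between,
    )


def system_type_segregation(m: ConnectivityMatrix, p: SystemPartition,
                            system_type: str, *, _precomputed=None) -> float:
    """Mean-of-means segregation restricted to systems of one type.

    ``Bs`` of each system includes pairs to systems of the other type; only
    systems of the requested type with >= 2 nodes enter the grand means.
    """
    if _precomputed is None:
        _check_alignment(m, p)
        systems, sums, counts = _pair_sums(m, p)
    else:
        systems, sums, counts = _precomputed
    S = len(systems)
    diag = np.eye(S, dtype=bool)
    ws_list: list[float] = []
    bs_list: list[float] = []
    for i, s in enumerate(systems):
        if p.type_of_system[s] != system_type or counts[i, i] < 1:
            continue
        ws_list.append(sums[i, i] / counts[i, i])
        off = ~diag[i]
        n_off = counts[i, off].sum()
        bs_list.append(sums[i, off].sum() / n_off if n_off > 0 else np.nan)
    if not ws_list:
        raise FormatError(
            f"no system of type {system_type!r} with >= 2 nodes"
        )
    grand_w = float(np.mean(ws_list))
    grand_b = float(np.mean(bs_list))
    if grand_w == 0.0:
        raise UndefinedSegregationError(
            f"grand mean within-system z of type {system_type!r} is zero"
        )
    return (grand_w - grand_b) / grand_w


def mean_interactions(m: ConnectivityMatrix, p: SystemPartition) -> tuple[float, float]:
    """Grand means of per-system within (Ws) and between (Bs) connectivity.

    Aggregates across all assigned systems of both types; used for the
    within- vs between-system interaction-type analysis.
    """
    _check_alignment(m, p)
    systems, sums, counts = _pair_sums(m, p)
    S = len(systems)
    diag = np.eye(S, dtype=bool)
    ws_list, bs_list = [], []
    for i in range(S):
        if counts[i, i] >= 1:
            ws_list.append(sums[i, i] / counts[i, i])
        off = ~diag[i]
        n_off = counts[i, off].sum()
        if n_off > 0:
            bs_list.append(sums[i, off].sum() / n_off)
    if not ws_list or not bs_list:
        raise FormatError("partition yields no within or no between pairs")
    return float(np.mean(ws_list)), float(np.mean(bs_list))


def block_matrix(m: ConnectivityMatrix, p: SystemPartition) -> BlockMatrix:
    """System x system block means over exactly the node pairs in each block.

    Within blocks of 1-node systems are undefined and returned as NaN;
    missing values propagate, never silently become zero.
    """
    _check_alignment(m, p)
    systems, sums, counts = _pair_sums(m, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)
    means = (means + means.T) / 2.0
    return BlockMatrix(systems=tuple(systems), block_means=means)
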
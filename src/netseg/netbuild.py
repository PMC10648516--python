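"""Construction of subject-level functional connectivity matrices.

The matrix is the pairwise Fisher z-transformed Pearson correlation of the
node time series; negative values are then set to zero (global signal
regression induces spurious negative correlations) and no edge-density
thresholding is applied. The diagonal is structurally excluded: it is
stored as zero but never enters any pooled mean, which is guaranteed by the
pair-mask machinery in :mod:`netseg.segmetrics`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Correlations are clipped to this magnitude before the z-transform so a
#: duplicated node (r = 1) still yields a finite entry.
R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z connectivity matrix.

    The diagonal is excluded from all computations; it is stored as 0 purely
    as a placeholder.
    """

    values: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise FormatError("matrix shape does not match node_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise FormatError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("connectivity matrix contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle entries (each unordered pair once)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.node_ids),
                            columns=list(self.node_ids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="node_id")

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(dtype=float),
                   node_ids=tuple(str(c) for c in df.columns))


def average_members(member_ts: np.ndarray, membership: list[str] | np.ndarray,
                    node_order: list[str] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Average member (e.g. vertex) time series into node time series.

    ``membership[j]`` names the node that member column ``j`` belongs to.
    Returns ``(frames x nodes array, node_ids)`` with nodes in
    ``node_order`` (default: first appearance order). Every node must have
    at least one member.
    """
    member_ts = np.asarray(member_ts, dtype=float)
    membership = np.asarray(membership, dtype=object)
    if member_ts.ndim != 2 or member_ts.shape[1] != membership.shape[0]:
        raise FormatError("membership length must equal member column count")
    if node_order is None:
        node_order = list(dict.fromkeys(membership))
    out = np.empty((member_ts.shape[0], len(node_order)))
    for k, node in enumerate(node_order):
        cols = np.flatnonzero(membership == node)
        if cols.size == 0:
            raise FormatError(f"node {node!r} has no member series")
        out[:, k] = member_ts[:, cols].mean(axis=1)
    return out, tuple(str(n) for n in node_order)


def correlation_matrix(node_ts: np.ndarray,
                       node_ids: tuple[str, ...] | None = None) -> ConnectivityMatrix:
    """Pairwise Fisher z-transformed Pearson correlations of node series.

    Correlations are clipped to ``|r| <= 1 - 1e-7`` before ``atanh`` so
    degenerate duplicated signals stay finite (a log message records the
    clip). A node with zero variance is an error naming the node.
    """
    x = np.asarray(node_ts, dtype=float)
    if x.ndim != 2:
        raise FormatError("node time series must be frames x nodes")
    if x.shape[0] < 3:
        raise FormatError("need >= 3 frames to correlate")
    if node_ids is None:
        node_ids = tuple(f"node_{j + 1:03d}" for j in range(x.shape[1]))
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise FormatError(
            f"zero-variance node(s): {[node_ids[j] for j in dead]}"
        )
    r = np.corrcoef(x, rowvar=False)
    clipped = np.abs(r) > R_CLIP
    np.fill_diagonal(clipped, False)
    if clipped.any():
        logger.info("%d correlations clipped at |r| = %g", clipped.sum() // 2, R_CLIP)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(values=z, node_ids=tuple(node_ids))


def zero_negatives(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Set every negative entry to zero; no density thresholding follows."""
    return replace(m, values=np.maximum(m.values, 0.0))
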
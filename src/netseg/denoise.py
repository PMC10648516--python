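"""RSFC-specific denoising of node-level BOLD time series.

The processing order is fixed and enforced:

1. demean and detrend every node series;
2. multiple regression against nuisance signals (global signal, tissue
   surrogates, their first differences, and the Friston-24 motion set),
   with coefficients estimated on low-motion frames only;
3. scrubbing — frames with framewise displacement (FD) above threshold are
   censored and temporarily replaced by linear interpolation so that
   temporal filtering stays valid;
4. zero-phase band-pass filtering (default 0.009-0.08 Hz);
5. removal of the interpolated frames.

Quality control then excludes runs with fewer than ``min_frames`` clean
frames and truncates survivors to the first ``n_select`` clean frames so
every retained subject contributes the same amount of data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import signal as sps

from .errors import (
    AllFramesCensoredError,
    DesignMatrixError,
    FormatError,
    PipelineOrderError,
)

logger = logging.getLogger(__name__)

#: Default head radius (mm) used to convert rotations to displacements.
DEFAULT_HEAD_RADIUS_MM = 50.0

CLEAN, CENSORED, INTERPOLATED = 0, 1, 2
_STATUS_NAMES = {CLEAN: "clean", CENSORED: "censored", INTERPOLATED: "interpolated"}


class Stage(IntEnum):
    """Denoising stages in mandated order."""

    RAW = 0
    DETRENDED = 1
    REGRESSED = 2
    SCRUBBED = 3
    FILTERED = 4
    TRIMMED = 5


@dataclass
class BoldTimeSeries:
    """Frames x nodes signal matrix with acquisition metadata.

    ``frame_status`` holds one code per frame (clean / censored /
    interpolated); ``stage`` records the last denoising stage applied and is
    used to enforce the processing order.
    """

    data: np.ndarray
    tr: float
    frame_status: np.ndarray = field(default=None)  # type: ignore[assignment]
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("time series must be a 2-D frames x nodes array")
        if self.tr <= 0:
            raise FormatError("tr must be positive")
        if self.frame_status is None:
            self.frame_status = np.full(self.n_frames, CLEAN, dtype=np.int8)
        else:
            self.frame_status = np.asarray(self.frame_status, dtype=np.int8)
        if self.frame_status.shape != (self.n_frames,):
            raise FormatError("frame_status length must equal frame count")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("time series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_clean(self) -> int:
        return int(np.sum(self.frame_status == CLEAN))

    @property
    def n_censored(self) -> int:
        return int(np.sum(self.frame_status != CLEAN))


def _require_stage(ts: BoldTimeSeries, expected: Stage, op: str) -> None:
    if ts.stage != expected:
        raise PipelineOrderError(
            f"{op} expects a time series at stage {expected.name}, "
            f"got {ts.stage.name}; the denoising order is fixed"
        )


@dataclass
class MotionTrace:
    """Rigid-body motion parameters and derived framewise displacement."""

    params: np.ndarray          # frames x 6: 3 translations mm, 3 rotations rad
    fd: np.ndarray              # per-frame FD, mm; fd[0] == 0 by convention

    @classmethod
    def from_params(cls, params: np.ndarray,
                    head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> "MotionTrace":
        return cls(params=np.asarray(params, dtype=float),
                   fd=compute_fd(params, head_radius))


@dataclass
class NuisanceSet:
    """Design matrix of nuisance regressors with column names."""

    regressors: np.ndarray      # frames x k
    names: list[str]

    @property
    def k(self) -> int:
        return self.regressors.shape[1]


def compute_fd(params: np.ndarray,
               head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement from 6 rigid-body parameters.

    ``FD(t) = sum_i |d trans_i(t)| + sum_j head_radius * |d rot_j(t)|`` with
    backward differences; the first frame has FD 0 by convention. Rotations
    (radians) are converted to arc length on a sphere of ``head_radius`` mm.
    """
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise FormatError("motion parameters must be a frames x 6 table")
    if p.shape[0] < 2:
        raise FormatError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(p, axis=0))
    fd = np.empty(p.shape[0])
    fd[0] = 0.0
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return fd


def _backward_diff(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[1:] = np.diff(x, axis=0)
    return out


def build_nuisance(ts: BoldTimeSeries, motion: MotionTrace,
                   tissue_surrogates: np.ndarray | None = None) -> NuisanceSet:
    """Assemble the nuisance design: global signal, tissue surrogates, their
    first differences, and the Friston-24 motion expansion (6 parameters,
    their one-frame differences, and the squares of both).

    The global signal is the mean over all nodes of ``ts``. Degenerate
    columns (all zero, or duplicating an earlier column) are dropped with a
    warning so the design stays full rank; the intercept/trend terms are
    handled by the earlier detrending stage, not here.
    """
    n = ts.n_frames
    if motion.params.shape[0] != n:
        raise FormatError("motion trace frame count differs from time series")
    cols: list[np.ndarray] = []
    names: list[str] = []

    gs = ts.data.mean(axis=1)
    tissues = [("global_signal", gs)]
    if tissue_surrogates is not None:
        tiss = np.atleast_2d(np.asarray(tissue_surrogates, dtype=float))
        if tiss.shape[0] != n:
            tiss = tiss.T
        if tiss.shape[0] != n:
            raise FormatError("tissue surrogates frame count differs from time series")
        for j in range(tiss.shape[1]):
            label = ["white_matter", "csf"][j] if j < 2 else f"tissue_{j}"
            tissues.append((label, tiss[:, j]))
    for label, sig in tissues:
        cols.append(sig)
        names.append(label)
    for label, sig in tissues:
        cols.append(_backward_diff(sig))
        names.append(f"d_{label}")

    mp = motion.params
    dmp = _backward_diff(mp)
    for j in range(6):
        cols.append(mp[:, j]); names.append(f"motion_{j + 1}")
    for j in range(6):
        cols.append(dmp[:, j]); names.append(f"d_motion_{j + 1}")
    for j in range(6):
        cols.append(mp[:, j] ** 2); names.append(f"motion_{j + 1}_sq")
    for j in range(6):
        cols.append(dmp[:, j] ** 2); names.append(f"d_motion_{j + 1}_sq")

    X = np.column_stack(cols)
    # Vectorized degenerate-column screen: all-zero columns, then exact
    # duplicates of an earlier column (element-wise within tolerance).
    tol = 1e-8
    zero = np.max(np.abs(X), axis=0) <= tol
    diff = np.max(np.abs(X[:, :, None] - X[:, None, :]), axis=0)
    dup_of_earlier = np.any(np.tril(diff <= tol, k=-1), axis=1)
    keep: list[int] = []
    for j in range(X.shape[1]):
        if zero[j]:
            logger.warning("dropping all-zero nuisance column %s", names[j])
        elif dup_of_earlier[j]:
            logger.warning("dropping duplicate nuisance column %s", names[j])
        else:
            keep.append(j)
    return NuisanceSet(regressors=X[:, keep], names=[names[j] for j in keep])


def demean_detrend(ts: BoldTimeSeries) -> BoldTimeSeries:
    """Remove the per-node best-fit line (mean and linear trend)."""
    _require_stage(ts, Stage.RAW, "demean_detrend")
    if ts.n_frames < 3:
        raise FormatError("need >= 3 frames to detrend")
    detrended = sps.detrend(ts.data, axis=0, type="linear")
    return replace(ts, data=detrended, frame_status=ts.frame_status.copy(),
                   stage=Stage.DETRENDED)


def regress_nuisance(ts: BoldTimeSeries, nuisance: NuisanceSet,
                     censor_mask: np.ndarray | None = None) -> BoldTimeSeries:
    """Regress the nuisance design out of every node series.

    Coefficients are estimated on non-censored frames only
    (``censor_mask`` True marks frames to exclude from the fit), then the
    fitted nuisance component is subtracted from *all* frames so censored
    frames remain consistent for interpolation and filtering.
    """
    _require_stage(ts, Stage.DETRENDED, "regress_nuisance")
    X = nuisance.regressors
    if X.shape[0] != ts.n_frames:
        raise FormatError("nuisance design frame count differs from time series")
    if censor_mask is None:
        censor_mask = np.zeros(ts.n_frames, dtype=bool)
    censor_mask = np.asarray(censor_mask, dtype=bool)
    good = ~censor_mask
    if good.sum() <= X.shape[1]:
        raise DesignMatrixError("fewer clean frames than nuisance regressors")
    Xg = X[good]
    beta, _, rank, _ = np.linalg.lstsq(Xg, ts.data[good], rcond=None)
    if rank < X.shape[1]:
        # Identify offending columns by greedy rank growth.
        bad: list[str] = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = Xg[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(nuisance.names[j])
        raise DesignMatrixError(
            f"nuisance design is rank deficient; collinear columns: {bad}"
        )
    residuals = ts.data - X @ beta
    return replace(ts, data=residuals, frame_status=ts.frame_status.copy(),
                   stage=Stage.REGRESSED)


def censor_and_interpolate(ts: BoldTimeSeries, fd: np.ndarray,
                           threshold: float = 0.3) -> BoldTimeSeries:
    """Flag frames with FD above threshold and fill them by linear
    interpolation between flanking clean frames (edge gaps take the nearest
    clean value), so band-pass filtering sees a gap-free series."""
    _require_stage(ts, Stage.REGRESSED, "censor_and_interpolate")
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (ts.n_frames,):
        raise FormatError("fd length must equal frame count")
    bad = fd > threshold
    if bad.all():
        raise AllFramesCensoredError("every frame exceeds the FD threshold")
    data = ts.data.copy()
    if bad.any():
        idx = np.arange(ts.n_frames)
        good_idx = idx[~bad]
        bad_idx = idx[bad]
        # Vectorized linear interpolation between flanking clean frames;
        # edge gaps take the nearest clean value.
        hi = np.clip(np.searchsorted(good_idx, bad_idx), 0, good_idx.size - 1)
        lo = np.clip(hi - 1, 0, good_idx.size - 1)
        left, right = good_idx[lo], good_idx[hi]
        span = np.where(right > left, right - left, 1)
        w = np.clip((bad_idx - left) / span, 0.0, 1.0)
        data[bad] = (1.0 - w[:, None]) * data[left] + w[:, None] * data[right]
    status = np.where(bad, INTERPOLATED, CLEAN).astype(np.int8)
    return replace(ts, data=data, frame_status=status, stage=Stage.SCRUBBED)


def bandpass(ts: BoldTimeSeries, low: float = 0.009,
             high: float = 0.08) -> BoldTimeSeries:
    """Zero-phase Butterworth band-pass (order 2, applied forward-backward)."""
    _require_stage(ts, Stage.SCRUBBED, "bandpass")
    nyquist = 0.5 / ts.tr
    if not (0.0 < low < high < nyquist):
        raise FormatError(
            f"band ({low}, {high}) Hz infeasible for TR {ts.tr} s "
            f"(Nyquist {nyquist:.4f} Hz)"
        )
    b, a = sps.butter(2, [low, high], btype="bandpass", fs=1.0 / ts.tr)
    filtered = sps.filtfilt(b, a, ts.data, axis=0)
    return replace(ts, data=filtered, frame_status=ts.frame_status.copy(),
                   stage=Stage.FILTERED)


def drop_interpolated(ts: BoldTimeSeries) -> BoldTimeSeries:
    """Remove censored/interpolated frames, preserving order."""
    _require_stage(ts, Stage.FILTERED, "drop_interpolated")
    keep = ts.frame_status == CLEAN
    return replace(
        ts,
        data=ts.data[keep],
        frame_status=np.full(int(keep.sum()), CLEAN, dtype=np.int8),
        stage=Stage.TRIMMED,
    )


@dataclass
class QCVerdict:
    """Outcome of the frame-count quality check for one run."""

    retained: bool
    clean_frames: int
    reason: str = ""


def qc_and_select(ts: BoldTimeSeries, min_frames: int = 100,
                  n_select: int = 100) -> tuple[BoldTimeSeries | None, QCVerdict]:
    """Exclude runs with fewer than ``min_frames`` clean frames; otherwise
    return exactly the first ``n_select`` clean frames."""
    _require_stage(ts, Stage.TRIMMED, "qc_and_select")
    n_clean = ts.n_frames
    if n_clean < min_frames:
        return None, QCVerdict(
            retained=False, clean_frames=n_clean,
            reason=f"<{min_frames} clean frames after scrubbing",
        )
    selected = replace(
        ts,
        data=ts.data[:n_select],
        frame_status=np.full(min(n_select, n_clean), CLEAN, dtype=np.int8),
        stage=Stage.TRIMMED,
    )
    return selected, QCVerdict(retained=True, clean_frames=n_clean)


@dataclass
class DenoiseResult:
    """Everything the downstream stages need from one denoised run."""

    ts: BoldTimeSeries | None
    verdict: QCVerdict
    mean_fd_pre: float
    mean_fd_post: float | None
    pct_frames_lost: float
    n_frames_in: int


def denoise_subject(
    data: np.ndarray,
    motion_params: np.ndarray,
    tr: float,
    tissue_surrogates: np.ndarray | None = None,
    fd_threshold: float = 0.3,
    band: tuple[float, float] = (0.009, 0.08),
    min_frames: int = 100,
    n_select: int = 100,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
) -> DenoiseResult:
    """Run the full ordered denoising sequence for one subject."""
    ts = BoldTimeSeries(data=data, tr=tr)
    motion = MotionTrace.from_params(motion_params, head_radius)
    censor = motion.fd > fd_threshold

    ts = demean_detrend(ts)
    nuisance = build_nuisance(ts, motion, tissue_surrogates)
    ts = regress_nuisance(ts, nuisance, censor_mask=censor)
    ts = censor_and_interpolate(ts, motion.fd, threshold=fd_threshold)
    ts = bandpass(ts, *band)
    ts = drop_interpolated(ts)
    selected, verdict = qc_and_select(ts, min_frames=min_frames, n_select=n_select)

    clean_mask = ~censor
    mean_fd_pre = float(motion.fd.mean())
    mean_fd_post = float(motion.fd[clean_mask].mean()) if clean_mask.any() else None
    pct_lost = 100.0 * float(censor.mean())
    return DenoiseResult(
        ts=selected,
        verdict=verdict,
        mean_fd_pre=mean_fd_pre,
        mean_fd_post=mean_fd_post,
        pct_frames_lost=pct_lost,
        n_frames_in=data.shape[0],
    )
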
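"""Synthetic cohort generator for aging/dementia connectivity studies.

Emulates a cross-sectional cohort of older adults (ages 55-96) spanning
Clinical Dementia Rating (CDR) levels 0, 0.5, 1 and 2, together with
node-level BOLD-like time series whose correlation structure carries the
effects of interest:

* modular ("stochastic block") covariance — within-system correlations
  exceed between-system correlations;
* age linearly weakens within-system coupling of association systems;
* dementia severity (CDR) weakens within-system coupling of both system
  types and strengthens a structured subset of between-system couplings;
* head-motion spikes whose per-frame probability grows with CDR, so more
  impaired participants lose more frames to scrubbing.

Effects are injected linearly on the Fisher-z scale and converted to
correlations for sampling. Every draw is governed by a single master seed:
per-subject generators are spawned from it, so enlarging the cohort never
reshuffles earlier subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedSegregationError
from .partition import ASSOCIATION, SystemPartition

logger = logging.getLogger(__name__)

#: Reference age (years) at which the age effect is zero; slopes act on
#: deviations from this anchor so the baseline z-values describe a typical
#: participant rather than a newborn.
AGE_REFERENCE = 75.0

#: Correlations are kept inside this bound after effect injection.
R_CLIP = 0.99


@dataclass
class SubjectRecord:
    """Covariates of one synthetic participant."""

    subject_id: str
    age: float                      # years
    cdr: float                      # dementia severity, one of {0, 0.5, 1, 2}
    gender: str                     # "F" or "M"
    education: float                # years, > 0
    pulse: float | None = None      # beats/min
    respiration: float | None = None  # breaths/min
    n_frames: int = 200             # frames acquired for this subject
    mean_fd_post: float | None = None  # mm, filled after denoising

    def __post_init__(self) -> None:
        if self.education <= 0:
            raise ConfigurationError("education must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Effect sizes injected into the generating covariance.

    All slopes act on the Fisher-z scale. ``age_slope_within_assoc`` applies
    to within-system blocks of association systems only, per year of age
    relative to :data:`AGE_REFERENCE`. The CDR slopes apply per CDR unit:
    ``cdr_slope_within`` to every within-system block, ``cdr_slope_between``
    to between-system blocks whose pair involves at least one system in
    ``cdr_between_systems`` (dementia-related hyperconnectivity concentrates
    on hub-like association systems rather than lifting every system pair
    uniformly; a uniform lift is indistinguishable from a global signal and
    would be removed by global signal regression downstream).
    """

    baseline_within_z: dict[str, float] = field(
        default_factory=lambda: {
            "default": 0.62,
            "frontoparietal": 0.58,
            "cingulo-opercular": 0.55,
            "dorsal-attention": 0.52,
            "ventral-attention": 0.50,
            "salience": 0.48,
            "visual": 0.70,
            "somatomotor-hand": 0.65,
            "somatomotor-mouth": 0.60,
            "auditory": 0.66,
        }
    )
    default_within_z: float = 0.55          # fallback for unlisted systems
    baseline_between_z: float = 0.12        # Fisher-z, association-association pairs
    baseline_between_z_sm: float = 0.04     # Fisher-z, pairs involving a sensory-motor system
    between_z_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    age_slope_within_assoc: float = -0.002  # dz per year, association within
    cdr_slope_between: float = 0.10         # dz per CDR unit, targeted between
    cdr_slope_within: float = -0.05         # dz per CDR unit, all within
    cdr_between_systems: tuple[str, ...] = ("default", "frontoparietal")
    noise_sd: float = 0.5                   # white measurement noise, signal units
    ar_coef: float = 0.5                    # temporal AR(1) of the neural signal
    spike_rate_base: float = 0.05           # motion-spike probability per frame
    spike_rate_cdr: float = 0.08            # added probability per CDR unit
    spike_translation_mm: float = 1.0       # excursion size, guarantees FD > 0.3
    spike_artifact_amp: float = 3.0         # global additive artifact at spikes

    def __post_init__(self) -> None:
        between = [self.baseline_between_z, self.baseline_between_z_sm,
                   *self.between_z_overrides.values()]
        within = [*self.baseline_within_z.values(), self.default_within_z]
        if max(between) >= min(within):
            raise ConfigurationError(
                "modular structure requires every baseline within-z to exceed "
                "every baseline between-z"
            )
        max_rate = self.spike_rate_base + self.spike_rate_cdr * 2.0
        if not (0.0 <= self.spike_rate_base <= 1.0 and 0.0 <= max_rate <= 1.0):
            raise ConfigurationError("spike rates must stay within [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.ar_coef < 1.0):
            raise ConfigurationError("ar_coef must lie in [0, 1)")

    def within_z(self, system: str) -> float:
        return self.baseline_within_z.get(system, self.default_within_z)

    def between_z(self, sys_a: str, sys_b: str,
                  type_a: str | None = None, type_b: str | None = None) -> float:
        key = (sys_a, sys_b) if (sys_a, sys_b) in self.between_z_overrides else (sys_b, sys_a)
        if key in self.between_z_overrides:
            return self.between_z_overrides[key]
        from .partition import SENSORY_MOTOR
        if SENSORY_MOTOR in (type_a, type_b):
            return self.baseline_between_z_sm
        return self.baseline_between_z

    def spike_rate(self, cdr: float) -> float:
        return float(np.clip(self.spike_rate_base + self.spike_rate_cdr * cdr, 0.0, 1.0))

    def null(self) -> "EffectSpec":
        """Copy with every covariate slope set to zero (null generator)."""
        return replace(
            self,
            age_slope_within_assoc=0.0,
            cdr_slope_between=0.0,
            cdr_slope_within=0.0,
            spike_rate_cdr=0.0,
        )


# Cohort composition targets. Group-conditional means/SDs reproduce the
# demographic gradient of a typical aging/dementia sample: higher CDR goes
# with older age and slightly lower education; CDR frequencies follow the
# 326 / 220 / 55 split of normal, very mild and mild-to-moderate dementia
# (the rarest level, CDR 2, is a small fraction of the combined 1-and-2
# group).
@dataclass(frozen=True)
class CohortSpec:
    """Configuration for :func:`generate_cohort`."""

    size: int = 601
    cdr_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    cdr_probs: tuple[float, ...] = (0.5424, 0.3661, 0.0749, 0.0166)
    age_range: tuple[float, float] = (55.0, 96.0)
    age_mean_by_cdr: tuple[float, ...] = (73.96, 74.98, 77.95, 77.95)
    age_sd_by_cdr: tuple[float, ...] = (7.75, 8.60, 7.48, 7.48)
    female_prop: float = 0.5324
    edu_mean_by_cdr: tuple[float, ...] = (16.97, 16.08, 15.42, 15.42)
    edu_sd: float = 2.45
    edu_range: tuple[float, float] = (6.0, 22.0)
    pulse_mean: float = 64.39
    pulse_sd: float = 10.31
    respiration_mean: float = 16.09
    respiration_sd: float = 2.36
    # Acquisition lengths (frames) and their mixing proportions, mirroring a
    # multi-protocol study in which runs hold 140, 197 or 200 frames.
    frame_counts: tuple[int, ...] = (140, 197, 200)
    frame_probs: tuple[float, ...] = (0.2, 0.2, 0.6)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigurationError("cohort size must be >= 1")
        for name, probs in (("cdr_probs", self.cdr_probs), ("frame_probs", self.frame_probs)):
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ConfigurationError(f"{name} must be nonnegative and sum to 1")
        if not (0.0 <= self.female_prop <= 1.0):
            raise ConfigurationError("female_prop must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")
        if len(self.cdr_levels) != len(self.cdr_probs):
            raise ConfigurationError("cdr_levels and cdr_probs differ in length")

    @property
    def mean_age(self) -> float:
        return float(np.dot(self.cdr_probs, self.age_mean_by_cdr))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (bounds are mild, so this is cheap)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def subject_seed_sequences(seed: int, size: int) -> list[np.random.SeedSequence]:
    """Spawn one independent seed stream per subject from the master seed."""
    return np.random.SeedSequence(seed).spawn(size)


def generate_cohort(spec: CohortSpec, seed: int) -> list[SubjectRecord]:
    """Draw a cohort of :class:`SubjectRecord` from the configured mixture.

    Age and education are drawn conditional on the sampled CDR level, so the
    cohort reproduces the usual confounding of age and dementia severity.
    Reproducible: the same ``(spec, seed)`` always yields the same cohort,
    and subject *i* is unchanged if ``spec.size`` grows.
    """
    streams = subject_seed_sequences(seed, spec.size)
    records: list[SubjectRecord] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        k = int(rng.choice(len(spec.cdr_levels), p=spec.cdr_probs))
        cdr = float(spec.cdr_levels[k])
        age = _truncated_normal(
            rng, spec.age_mean_by_cdr[k], spec.age_sd_by_cdr[k], *spec.age_range
        )
        gender = "F" if rng.random() < spec.female_prop else "M"
        education = _truncated_normal(
            rng, spec.edu_mean_by_cdr[k], spec.edu_sd, *spec.edu_range
        )
        pulse = float(rng.normal(spec.pulse_mean, spec.pulse_sd))
        respiration = float(rng.normal(spec.respiration_mean, spec.respiration_sd))
        n_frames = int(
            spec.frame_counts[int(rng.choice(len(spec.frame_counts), p=spec.frame_probs))]
        )
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:04d}",
                age=age,
                cdr=cdr,
                gender=gender,
                education=education,
                pulse=pulse,
                respiration=respiration,
                n_frames=n_frames,
            )
        )
    return records


def cohort_to_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "age": [s.age for s in cohort],
            "cdr": [s.cdr for s in cohort],
            "gender": [s.gender for s in cohort],
            "education": [s.education for s in cohort],
            "pulse": [s.pulse for s in cohort],
            "respiration": [s.respiration for s in cohort],
            "n_frames": [s.n_frames for s in cohort],
            "mean_fd_post": [s.mean_fd_post for s in cohort],
        }
    )


def _block_z_matrix(subject: SubjectRecord, partition: SystemPartition,
                    effects: EffectSpec) -> np.ndarray:
    """Block-constant Fisher-z matrix encoding the subject's effects."""
    systems = partition.systems()
    s_index = {s: i for i, s in enumerate(systems)}
    S = len(systems)
    d_age = subject.age - AGE_REFERENCE
    target = set(effects.cdr_between_systems)

    block_z = np.empty((S, S))
    for i, a in enumerate(systems):
        for j, b in enumerate(systems):
            if i == j:
                z = effects.within_z(a) + effects.cdr_slope_within * subject.cdr
                if partition.type_of_system[a] == ASSOCIATION:
                    z += effects.age_slope_within_assoc * d_age
            else:
                z = effects.between_z(
                    a, b, partition.type_of_system[a], partition.type_of_system[b]
                )
                if a in target or b in target:
                    z += effects.cdr_slope_between * subject.cdr
            block_z[i, j] = z

    labels = np.asarray([s_index[s] for s in partition.system_of_node])
    return block_z[np.ix_(labels, labels)]


def nearest_psd_correlation(r: np.ndarray) -> np.ndarray:
    """Repair an indefinite symmetric matrix by clipping eigenvalues at zero
    and renormalizing to unit diagonal."""
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def build_generating_covariance(
    subject: SubjectRecord,
    partition: SystemPartition,
    effects: EffectSpec,
) -> np.ndarray:
    """Subject-specific generating correlation matrix (unit diagonal).

    Within- and between-system blocks start at the baseline Fisher-z values
    and are shifted by the subject's age and CDR according to ``effects``;
    the block matrix is then mapped z -> r, clipped to ``(-R_CLIP, R_CLIP)``
    (with a log message if clipping fires) and repaired to the nearest
    positive semi-definite correlation matrix if needed.
    """
    z = _block_z_matrix(subject, partition, effects)
    r = np.tanh(z)
    if np.any(np.abs(r) > R_CLIP):
        n_clip = int(np.sum(np.abs(r) > R_CLIP) // 2)
        logger.warning(
            "subject %s: %d block correlations clipped to |r| <= %.2f",
            subject.subject_id, n_clip, R_CLIP,
        )
        r = np.clip(r, -R_CLIP, R_CLIP)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        r = nearest_psd_correlation(r)
    return r


@dataclass
class GroundTruth:
    """Noise-free generating quantities for parameter-recovery checks."""

    effects: EffectSpec
    expected_global: dict[str, float]
    expected_assoc: dict[str, float]
    expected_sensorimotor: dict[str, float]
    spike_rate: dict[str, float]


def expected_segregation(covariance: np.ndarray, partition: SystemPartition) -> float:
    """Noise-free system segregation of a generating covariance.

    Normalizes the covariance to correlations, Fisher z-transforms the
    off-diagonal entries, zeroes negatives, then enumerates every node pair
    of assigned systems: ``(mean within - mean between) / mean within``.
    Serves as the ground-truth oracle for the simulated cohorts.
    """
    cov = np.asarray(covariance, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n) or n != partition.n_nodes:
        raise ConfigurationError("covariance does not match partition size")
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    labels = partition.labels_array()
    assigned = partition.assigned_mask()

    within: list[float] = []
    between: list[float] = []
    for i in range(n):
        if not assigned[i]:
            continue
        for j in range(i + 1, n):
            if not assigned[j]:
                continue
            z = np.arctanh(np.clip(r[i, j], -1 + 1e-7, 1 - 1e-7))
            z = max(z, 0.0)
            (within if labels[i] == labels[j] else between).append(z)
    mean_w = float(np.mean(within))
    mean_b = float(np.mean(between))
    if mean_w == 0.0:
        raise UndefinedSegregationError("mean within-system connectivity is zero")
    return (mean_w - mean_b) / mean_w


def generate_subject_timeseries(
    subject: SubjectRecord,
    covariance: np.ndarray,
    n_frames: int,
    tr: float,
    effects: EffectSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
):
    """Simulate one subject's node time series, motion trace and tissue
    surrogate channels.

    Returns ``(data, motion, tissue, spike_frames)`` where ``data`` is
    ``n_frames x n_nodes`` (zero-mean multivariate normal draws with the
    given covariance plus white measurement noise and a global additive
    artifact at motion-spike frames), ``motion`` is ``n_frames x 6``
    rigid-body parameters (3 translations mm, 3 rotations rad) combining a
    slow physiological random walk with large spike excursions, and
    ``tissue`` is ``n_frames x 2`` white-matter / CSF surrogate channels
    that also carry the spike artifact.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    cov = np.asarray(covariance, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # PSD but singular (e.g. after eigenvalue-clipping repair): use an
        # eigen-factor instead of Cholesky.
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ConfigurationError("covariance must be positive semi-definite")
        chol = v * np.sqrt(np.clip(w, 0.0, None))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = cov.shape[0]
    draws = rng.standard_normal((n_frames, n_nodes)) @ chol.T
    phi = effects.ar_coef
    if phi > 0:
        # Stationary AR(1) in time with the target spatial covariance as the
        # marginal: BOLD power concentrates at low frequencies, so the
        # band-pass retains most of the neural signal.
        from scipy.signal import lfilter
        x0 = rng.standard_normal(n_nodes) @ chol.T
        data, _ = lfilter(
            [np.sqrt(1.0 - phi * phi)], [1.0, -phi], draws, axis=0,
            zi=(phi * x0)[None, :],
        )
    else:
        data = draws
    if effects.noise_sd > 0:
        data += effects.noise_sd * rng.standard_normal((n_frames, n_nodes))

    # Baseline motion: a random walk whose per-frame framewise displacement
    # averages roughly 0.1 mm, typical for compliant older adults.
    increments = np.empty((n_frames, 6))
    increments[:, :3] = 0.02 * rng.standard_normal((n_frames, 3))     # mm
    increments[:, 3:] = 0.0004 * rng.standard_normal((n_frames, 3))   # rad
    increments[0] = 0.0
    motion = np.cumsum(increments, axis=0)

    rate = effects.spike_rate(subject.cdr)
    spikes = rng.random(n_frames) < rate
    spikes[0] = False
    spike_frames = np.flatnonzero(spikes)
    if spike_frames.size:
        # Single-frame translation excursions: FD exceeds the scrubbing
        # threshold at the spike frame and at the frame after it.
        motion[spike_frames, 0] += effects.spike_translation_mm
        artifact = np.zeros(n_frames)
        artifact[spike_frames] = effects.spike_artifact_amp
        data += artifact[:, None]

    tissue = rng.standard_normal((n_frames, 2))
    if spike_frames.size:
        tissue += 0.5 * artifact[:, None]
    return data, motion, tissue, spike_frames


def ground_truth_for(
    cohort: list[SubjectRecord],
    partition: SystemPartition,
    effects: EffectSpec,
) -> GroundTruth:
    """Expected (noise-free) segregation of every subject's generating matrix."""
    from .netbuild import ConnectivityMatrix, zero_negatives
    from .segmetrics import system_segregation

    expected_global: dict[str, float] = {}
    expected_assoc: dict[str, float] = {}
    expected_sm: dict[str, float] = {}
    spike_rate: dict[str, float] = {}
    for subject in cohort:
        cov = build_generating_covariance(subject, partition, effects)
        z = np.arctanh(np.clip(cov, -1 + 1e-7, 1 - 1e-7))
        np.fill_diagonal(z, 0.0)
        m = zero_negatives(ConnectivityMatrix(values=z, node_ids=partition.node_ids))
        res = system_segregation(m, partition)
        expected_global[subject.subject_id] = res.global_segregation
        expected_assoc[subject.subject_id] = res.assoc_segregation
        expected_sm[subject.subject_id] = res.sensorimotor_segregation
        spike_rate[subject.subject_id] = effects.spike_rate(subject.cdr)
    return GroundTruth(
        effects=effects,
        expected_global=expected_global,
        expected_assoc=expected_assoc,
        expected_sensorimotor=expected_sm,
        spike_rate=spike_rate,
    )
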
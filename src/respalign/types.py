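"""Domain containers shared across the pipeline.

All times are in seconds on the recording clock (t = 0 at the start of the
recording unless a trace says otherwise).  Respiratory phase is an angle in
[0, 2*pi): 0 at inspiration onset, pi at peak inhalation, approaching 2*pi at
the end of expiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


class SegmentationError(RuntimeError):
    """Raised when a respiration trace cannot be segmented into cycles."""


class InsufficientDataError(RuntimeError):
    """Raised when too few cycles/participants are available for a procedure."""


@dataclass
class RespirationTrace:
    """Uniformly sampled continuous respiration amplitude.

    Parameters
    ----------
    samples:
        Amplitude values in arbitrary units (thermistor voltage, belt
        displacement, ...).  Gaps are not representable: a missing-sample file
        is a load-time error.
    fs:
        Sampling rate in Hz.
    t0:
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace must be a single channel (1-D)")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains missing or non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class CycleSet:
    """Segmented respiratory cycles (trough -> peak -> trough landmarks).

    Cycles tile the segmented part of the trace: ``end_s[i] == onset_s[i+1]``
    (shared trough).  ``distance`` and ``atypical`` are filled by the
    atypicality screen and are NaN/False before it runs.
    """

    onset_s: np.ndarray
    peak_s: np.ndarray
    end_s: np.ndarray
    distance: np.ndarray = field(default=None)  # type: ignore[assignment]
    atypical: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.peak_s = np.asarray(self.peak_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        if self.distance is None:
            self.distance = np.full(self.n_cycles, np.nan)
        if self.atypical is None:
            self.atypical = np.zeros(self.n_cycles, dtype=bool)
        self.distance = np.asarray(self.distance, dtype=float)
        self.atypical = np.asarray(self.atypical, dtype=bool)
        if not (self.onset_s < self.peak_s).all() or not (self.peak_s < self.end_s).all():
            raise ValueError("each cycle needs onset < peak < end")
        if self.n_cycles > 1 and not np.allclose(self.end_s[:-1], self.onset_s[1:]):
            raise ValueError("cycles must tile the trace (shared troughs)")

    @property
    def n_cycles(self) -> int:
        return self.onset_s.size

    @property
    def durations(self) -> np.ndarray:
        return self.end_s - self.onset_s

    def containing(self, t: float) -> int:
        """Index of the cycle whose half-open span [onset, end) contains t, or -1."""
        i = int(np.searchsorted(self.onset_s, t, side="right")) - 1
        if i < 0 or t >= self.end_s[i]:
            return -1
        return i


@dataclass
class PhaseSeries:
    """Piecewise-linear respiratory phase on a uniform analysis grid.

    ``valid`` is False outside complete cycles and inside atypical ones.
    """

    phase: np.ndarray
    valid: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.phase.shape != self.valid.shape:
            raise ValueError("phase and valid must align")

    @property
    def n_samples(self) -> int:
        return self.phase.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class EpochedPhase:
    """Trials x time matrix of phase around stimulus onsets.

    ``rel_times`` runs from window start to window end at the analysis rate,
    identical for every trial; cells without valid phase coverage are masked.
    """

    phase: np.ndarray  # (n_trials, n_times), radians in [0, 2*pi)
    valid: np.ndarray  # (n_trials, n_times) bool
    rel_times: np.ndarray  # (n_times,) seconds relative to onset
    fs: float

    def __post_init__(self) -> None:
        self.phase = np.atleast_2d(np.asarray(self.phase, dtype=float))
        self.valid = np.atleast_2d(np.asarray(self.valid, dtype=bool))
        self.rel_times = np.asarray(self.rel_times, dtype=float)
        if self.phase.shape != self.valid.shape:
            raise ValueError("phase and valid must align")
        if self.phase.shape[1] != self.rel_times.size:
            raise ValueError("time axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    @property
    def n_times(self) -> int:
        return self.phase.shape[1]


@dataclass
class PlvsResult:
    """Phase-locking vector strength trace for one participant x condition.

    plvs(t) = | mean_j exp(i * phi_j(t)) | over valid trials j; NaN where fewer
    than ``min_trials`` trials contribute.
    """

    rel_times: np.ndarray
    plvs: np.ndarray
    n_trials: np.ndarray
    min_trials: int = 10

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=float)
        self.plvs = np.asarray(self.plvs, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        finite = self.plvs[np.isfinite(self.plvs)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("plvs out of [0, 1]")


@dataclass
class SurrogateNull:
    """Time-shift surrogate null for the group-mean plvs trace.

    ``threshold`` is the ``conf`` quantile of the per-iteration maxima over
    time, i.e. a family-wise corrected significance level of 1 - conf.
    """

    maxima: np.ndarray
    threshold: float
    n_iter: int
    conf: float
    observed: np.ndarray | None = None
    rel_times: np.ndarray | None = None

    def significant(self) -> np.ndarray:
        if self.observed is None:
            raise ValueError("no observed trace attached")
        return self.observed > self.threshold


@dataclass
class Cluster:
    """One supra-threshold cluster from the sign-flip permutation test."""

    t_start_s: float
    t_end_s: float
    sign: int
    max_sum_stat: float
    p_value: float
    cohens_d_at_peak: float
    peak_time_s: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_randomizations: int
    alpha_form: float
    t_crit: float
    min_cluster_s: float
    rel_times: np.ndarray
    t_values: np.ndarray

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters]


@dataclass
class PairedTResult:
    """Paired t-test with Cohen's D = mean(diff) / SD(diff, n-1 denominator)."""

    t: float
    p: float
    dof: int
    cohens_d: float
    mean_diff: float


@dataclass
class AngularTestResult:
    """Angular condition-difference randomization test with percentile CI."""

    mean_diff_rad: float
    ci_low: float
    ci_high: float
    p_value: float
    n_rand: int
    conf: float
    seed: int | None = None
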
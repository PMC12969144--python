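"""Phase-locking vector strength (plvs) and its inference machinery.

plvs at time t is the length of the trial-averaged unit phase vector,
| (1/n) sum_j exp(i * phi_j(t)) |: 1 when every trial shows the same phase, 0
when phases are uniformly dispersed.  Significance of the group-mean trace is
assessed against a time-shift surrogate null with max-over-time family-wise
correction; condition contrasts use a cluster-based sign-flip permutation test
(paired t cluster-forming, max-sum statistic, 250 ms minimum extent).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import (
    Cluster,
    ClusterTestResult,
    EpochedPhase,
    InsufficientDataError,
    PairedTResult,
    PlvsResult,
    SurrogateNull,
)


def plvs(epochs: EpochedPhase, min_trials: int = 10) -> PlvsResult:
    """plvs trace over the epoch time axis for one participant x condition.

    Masked cells are excluded from the vector average with the trial count
    adjusted per time point; time points with fewer than ``min_trials`` valid
    trials are reported as NaN (undefined), never as 0.
    """
    unit = np.exp(1j * epochs.phase) * epochs.valid
    counts = epochs.valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.abs(unit.sum(axis=0)) / counts
    vals = np.where(counts >= max(min_trials, 1), vals, np.nan)
    return PlvsResult(rel_times=epochs.rel_times, plvs=vals,
                      n_trials=counts, min_trials=min_trials)


def _group_mean(traces: np.ndarray) -> np.ndarray:
    """Complete-case group mean over participants (NaN where any is missing)."""
    return np.where(np.isnan(traces).any(axis=0), np.nan, traces.mean(axis=0))


def surrogate_threshold(
    epochs_by_participant: list[EpochedPhase],
    n_iter: int = 4000,
    conf: float = 0.99,
    seed: int | None = None,
    min_trials: int = 10,
) -> SurrogateNull:
    """Time-shift surrogate null for the group-mean plvs trace.

    Each iteration circularly shifts every trial's phase epoch (with its
    validity mask) by an independent uniform lag over the window, recomputes
    each participant's plvs trace, averages across participants, and takes the
    maximum over time.  The corrected threshold is the ``conf`` quantile of
    these maxima: group-mean plvs above it is significant at p < 1 - conf,
    corrected for multiple comparisons over time.
    """
    if n_iter < 100:
        import warnings

        warnings.warn(f"n_iter={n_iter} gives an unstable extreme quantile",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    P = len(epochs_by_participant)
    if P == 0:
        raise InsufficientDataError("no participants")
    T = epochs_by_participant[0].n_times
    rel_times = epochs_by_participant[0].rel_times

    units = [np.exp(1j * e.phase) * e.valid for e in epochs_by_participant]
    valids = [e.valid.astype(float) for e in epochs_by_participant]

    observed = _group_mean(
        np.vstack([plvs(e, min_trials=min_trials).plvs for e in epochs_by_participant])
    )

    maxima = np.empty(n_iter)
    done = 0
    while done < n_iter:
        # batch iterations to bound the gather tensor at ~32 MB
        n_max = max(e.n_trials for e in epochs_by_participant)
        B = int(np.clip(2_000_000 // max(n_max * T, 1), 1, n_iter - done))
        acc = np.zeros((B, T))
        bad = np.zeros((B, T), dtype=bool)
        for U, V in zip(units, valids):
            n = U.shape[0]
            shifts = rng.integers(0, T, size=(B, n))
            gidx = (np.arange(T)[None, None, :] - shifts[:, :, None]) % T
            rows = np.arange(n)[None, :, None]
            s = U[rows, gidx].sum(axis=1)
            c = V[rows, gidx].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                tr = np.abs(s) / c
            low = c < max(min_trials, 1)
            tr = np.where(low, 0.0, tr)
            bad |= low
            acc += tr
        group = np.where(bad, -np.inf, acc / P)
        maxima[done : done + B] = group.max(axis=1)
        done += B

    threshold = float(np.quantile(maxima, conf))
    return SurrogateNull(maxima=maxima, threshold=threshold, n_iter=n_iter,
                         conf=conf, observed=observed, rel_times=rel_times)


def _find_clusters(t_vals: np.ndarray, t_crit: float, min_len: int):
    """Maximal runs of same-sign supra-threshold samples of length >= min_len.

    Returns (start_idx, end_idx_inclusive, sign, sum_of_t) tuples; NaN samples
    (complete-case drops) break runs.
    """
    above = np.where(np.isfinite(t_vals) & (np.abs(t_vals) > t_crit),
                     np.sign(t_vals), 0.0)
    clusters = []
    i = 0
    n = above.size
    while i < n:
        s = above[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] == s:
            j += 1
        if j - i + 1 >= min_len:
            clusters.append((i, j, int(s), float(t_vals[i : j + 1].sum())))
        i = j + 1
    return clusters


def _t_traces(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired-t traces for many sign-flip patterns at once.

    Works on the (n_rand, P) sign matrix without materializing the
    (n_rand, P, T) tensor: squared differences are flip-invariant, so only the
    flipped mean varies per randomization.
    """
    P = diff.shape[0]
    sq = (diff**2).sum(axis=0)  # (T,)
    means = signs @ diff / P  # (R, T)
    var = (sq[None, :] - P * means**2) / (P - 1)
    var = np.clip(var, 1e-300, None)
    return means / np.sqrt(var / P)


def cluster_permutation(
    plvs_a: np.ndarray,
    plvs_b: np.ndarray,
    rel_times: np.ndarray,
    n_rand: int = 4000,
    alpha_form: float = 0.05,
    min_cluster_s: float = 0.25,
    seed: int | None = None,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Cluster-based sign-flip permutation test of plvs_a vs plvs_b.

    ``plvs_a`` and ``plvs_b`` are (participants x time) matrices of paired
    traces.  Per time point a paired t statistic of (a - b) is computed;
    candidate clusters are contiguous same-sign runs with |t| above the
    two-sided ``alpha_form`` critical value lasting at least ``min_cluster_s``.
    The cluster statistic is the within-run sum of t (max-sum); the null is the
    per-randomization maximum |cluster sum| under independent participant-wise
    sign flips of the condition difference.  p = (1 + exceedances)/(1 + n_rand),
    or the exact proportion over all 2^P patterns when ``exhaustive``.
    Cohen's D is reported at the time point of largest |group-mean difference|
    within each cluster, as mean(diff)/SD(diff) with the n-1 denominator.
    """
    a = np.atleast_2d(np.asarray(plvs_a, dtype=float))
    b = np.atleast_2d(np.asarray(plvs_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition matrices must have identical shape")
    P, T = a.shape
    if P < 2:
        raise InsufficientDataError("need >= 2 participants for a paired test")
    rel_times = np.asarray(rel_times, dtype=float)
    fs = 1.0 / float(np.median(np.diff(rel_times)))
    min_len = max(1, int(np.ceil(min_cluster_s * fs)))
    t_crit = float(stats.t.ppf(1.0 - alpha_form / 2.0, P - 1))

    diff = a - b
    complete = np.isfinite(diff).all(axis=0)
    diff_cc = np.where(complete[None, :], diff, 0.0)
    mean_d = diff_cc.mean(axis=0)
    sd_d = diff_cc.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_vals = mean_d / (sd_d / np.sqrt(P))
    t_vals = np.where(complete & (sd_d > 0), t_vals, np.nan)

    observed = _find_clusters(t_vals, t_crit, min_len)

    if exhaustive:
        if P > 20:
            raise ValueError("exhaustive enumeration limited to <= 20 participants")
        R = 2**P
        bits = (np.arange(R)[:, None] >> np.arange(P)[None, :]) & 1
        signs = np.where(bits == 1, 1.0, -1.0)
    else:
        rng = np.random.default_rng(seed)
        R = n_rand
        signs = rng.choice([-1.0, 1.0], size=(R, P))

    null_max = np.zeros(R)
    chunk = max(1, int(4_000_000 // max(T, 1)))
    for lo in range(0, R, chunk):
        tt = _t_traces(diff_cc, signs[lo : lo + chunk])
        tt[:, ~complete] = np.nan
        for r in range(tt.shape[0]):
            cl = _find_clusters(tt[r], t_crit, min_len)
            null_max[lo + r] = max((abs(c[3]) for c in cl), default=0.0)

    clusters = []
    for i, j, sign, ssum in observed:
        # tolerance so the identity sign pattern always counts as an exceedance
        # despite round-off between the vectorized and direct t computations
        thresh = abs(ssum) * (1.0 - 1e-9) - 1e-12
        if exhaustive:
            p = float((null_max >= thresh).sum()) / R
        else:
            p = (1.0 + float((null_max >= thresh).sum())) / (1.0 + R)
        seg = slice(i, j + 1)
        k = i + int(np.nanargmax(np.abs(mean_d[seg])))
        d_t = diff[:, k]
        sd_k = d_t.std(ddof=1)
        cohend = float(d_t.mean() / sd_k) if sd_k > 0 else np.inf * np.sign(d_t.mean())
        clusters.append(
            Cluster(
                t_start_s=float(rel_times[i]),
                t_end_s=float(rel_times[j]),
                sign=sign,
                max_sum_stat=ssum,
                p_value=p,
                cohens_d_at_peak=cohend,
                peak_time_s=float(rel_times[k]),
            )
        )
    return ClusterTestResult(
        clusters=clusters,
        n_randomizations=R,
        alpha_form=alpha_form,
        t_crit=t_crit,
        min_cluster_s=min_cluster_s,
        rel_times=rel_times,
        t_values=t_vals,
    )


def plvs_slope(
    values: np.ndarray | PlvsResult,
    rel_times: np.ndarray | None = None,
    pre_window: tuple[float, float] = (-2.0, -1.0),
    post_window: tuple[float, float] = (1.0, 2.0),
) -> float:
    """plvs slope: max over the post window minus min over the pre window.

    Indexes how sharply alignment builds toward the event; with the default
    windows it contrasts [-2, -1] s before onset with [+1, +2] s after.
    """
    if isinstance(values, PlvsResult):
        rel_times = values.rel_times
        values = values.plvs
    if rel_times is None:
        raise ValueError("rel_times required with a bare array")
    rel_times = np.asarray(rel_times, dtype=float)
    values = np.asarray(values, dtype=float)
    for w in (pre_window, post_window):
        if w[0] < rel_times[0] - 1e-9 or w[1] > rel_times[-1] + 1e-9:
            raise ValueError(f"window {w} lies outside the epoch")
    pre = values[(rel_times >= pre_window[0]) & (rel_times <= pre_window[1])]
    post = values[(rel_times >= post_window[0]) & (rel_times <= post_window[1])]
    if np.isnan(pre).all() or np.isnan(post).all():
        return float("nan")
    return float(np.nanmax(post) - np.nanmin(pre))


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> PairedTResult:
    """Paired t-test with Cohen's D = mean(diff)/SD(diff) (n-1 denominator).

    Zero-variance differences with nonzero mean yield an infinite D and an
    undefined (NaN) t; identical samples yield t = 0, D = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors required")
    n = a.size
    if n < 2:
        raise InsufficientDataError("need >= 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, p=1.0, dof=n - 1, cohens_d=0.0, mean_diff=0.0)
        return PairedTResult(t=np.nan, p=np.nan, dof=n - 1,
                             cohens_d=float(np.inf * np.sign(mean)), mean_diff=mean)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), p=p, dof=n - 1, cohens_d=mean / sd, mean_diff=mean)
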
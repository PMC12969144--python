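"""Respiration preprocessing: cycle segmentation, atypicality, phase.

A recording is segmented into breath cycles (trough -> peak -> trough) from
landmarks detected on a band-limited copy of the trace and refined on the raw
signal.  Cycles whose time-normalized waveform lies far from the centroid of
all cycles (breath holds, sighs) are flagged atypical.  Within each cycle the
respiratory phase rises linearly 0 -> pi over inhalation and pi -> 2*pi over
exhalation, and is evaluated directly on a 20 Hz analysis grid.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import (
    CycleSet,
    InsufficientDataError,
    PhaseSeries,
    RespirationTrace,
    SegmentationError,
    TWO_PI,
)


def _smooth(trace: RespirationTrace, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass used for landmark detection only."""
    nyq = trace.fs / 2.0
    if cutoff_hz >= nyq:
        return trace.samples.copy()
    sos = sps.butter(4, cutoff_hz / nyq, btype="low", output="sos")
    return sps.sosfiltfilt(sos, trace.samples)


def _refine(samples: np.ndarray, idx: np.ndarray, half_win: int, find_max: bool) -> np.ndarray:
    """Move each landmark to the signal extremum within +/- half_win samples."""
    out = np.empty_like(idx)
    n = samples.size
    for k, i in enumerate(idx):
        lo, hi = max(0, i - half_win), min(n, i + half_win + 1)
        seg = samples[lo:hi]
        out[k] = lo + (int(np.argmax(seg)) if find_max else int(np.argmin(seg)))
    return out


def _refine_troughs_kink(samples: np.ndarray, fs: float, idx: np.ndarray,
                         inner_s: float = 0.06, outer_s: float = 0.40,
                         max_shift_s: float = 0.20) -> np.ndarray:
    """Localize each trough as the intersection of its two linear flanks.

    Breath troughs are kinks (exhale runs into the next inhale), and low-pass
    smoothing shifts the apparent minimum toward the shallower flank when the
    adjacent cycles differ in duration.  Fitting a line to each flank outside
    the rounded tip and intersecting them recovers the kink position robustly
    against both smoothing bias and sample noise.
    """
    w_in = max(2, int(round(inner_s * fs)))
    w_out = max(w_in + 3, int(round(outer_s * fs)))
    n = samples.size
    out = idx.astype(float).copy()
    def fit_once(i: int) -> float | None:
        li, lo_ = max(0, i - w_out), i - w_in
        ri, ro = i + w_in, min(n, i + w_out + 1)
        if lo_ - li < 4 or ro - ri < 4:
            return None
        tl = np.arange(li, lo_) - i
        tr = np.arange(ri, ro) - i
        bl, al = np.polyfit(tl, samples[li:lo_], 1)
        br, ar = np.polyfit(tr, samples[ri:ro], 1)
        if br - bl <= 1e-12:  # flanks not forming a valley
            return None
        t_star = (al - ar) / (br - bl)
        if abs(t_star) > max_shift_s * fs:
            return None
        return i + t_star

    for k, i0 in enumerate(idx):
        est = fit_once(int(i0))
        if est is not None:
            out[k] = est
    return out


def segment_cycles(
    trace: RespirationTrace,
    min_cycle_s: float = 1.5,
    min_prominence_frac: float = 0.1,
    smooth_cutoff_hz: float = 2.0,
    refine_s: float = 0.25,
) -> CycleSet:
    """Detect trough-peak-trough landmarks and cut the trace into cycles.

    Peaks and troughs are found on a 2 Hz zero-phase low-passed copy with a
    prominence floor of ``min_prominence_frac`` times the robust amplitude
    range (5th-95th percentile) and a minimum trough spacing of
    ``min_cycle_s``; landmarks are then refined on the raw trace within
    +/- ``refine_s``.  Partial cycles at the recording edges are dropped.

    Raises
    ------
    SegmentationError
        If fewer than 3 complete cycles are found (e.g. a flat trace).
    """
    if trace.duration < 3 * min_cycle_s:
        raise SegmentationError(
            f"trace of {trace.duration:.1f} s is too short for 3 cycles of "
            f">= {min_cycle_s:.1f} s"
        )
    smooth = _smooth(trace, smooth_cutoff_hz)
    lo, hi = np.percentile(smooth, [5, 95])
    robust_range = hi - lo
    if robust_range <= 0:
        raise SegmentationError("trace has no amplitude variation (flat signal)")
    prominence = min_prominence_frac * robust_range
    dist = max(1, int(round(min_cycle_s * trace.fs)))

    troughs, _ = sps.find_peaks(-smooth, prominence=prominence, distance=dist)
    peaks, _ = sps.find_peaks(smooth, prominence=prominence)
    if troughs.size < 4 or peaks.size < 3:
        raise SegmentationError(
            f"found {troughs.size} troughs / {peaks.size} peaks; "
            "need at least 3 complete cycles"
        )
    # refine landmarks on band-limited signals: near its flat extrema the raw
    # trace is noise-dominated, so a raw argmin would jitter by ~100 ms
    half_win = max(1, int(round(refine_s * trace.fs)))
    troughs = np.unique(_refine(smooth, troughs, half_win, find_max=False))
    # a lighter low-pass keeps the trough kink sharp for flank intersection
    light = _smooth(trace, max(smooth_cutoff_hz, 8.0))
    trough_pos = _refine_troughs_kink(light, trace.fs, troughs)

    onsets, pk_list, ends = [], [], []
    for j in range(troughs.size - 1):
        a, b = troughs[j], troughs[j + 1]
        inside = peaks[(peaks > a) & (peaks < b)]
        if inside.size == 0:
            continue
        # the dominant peak between the two troughs marks peak inhalation
        p = inside[np.argmax(smooth[inside])]
        p = int(_refine(smooth, np.array([p]), half_win, find_max=True)[0])
        if trough_pos[j] < p < trough_pos[j + 1]:
            onsets.append(trough_pos[j])
            pk_list.append(float(p))
            ends.append(trough_pos[j + 1])
    if len(onsets) < 3:
        raise SegmentationError(f"only {len(onsets)} complete cycles detected")

    # enforce tiling (a cycle's end is the next cycle's onset) by keeping the
    # longest contiguous chain of trough-to-trough cycles
    onsets_a = np.asarray(onsets)
    ends_a = np.asarray(ends)
    chains: list[list[int]] = [[0]]
    for i in range(1, onsets_a.size):
        if onsets_a[i] == ends_a[i - 1]:
            chains[-1].append(i)
        else:
            chains.append([i])
    best = max(chains, key=len)
    if len(best) < 3:
        raise SegmentationError("no contiguous run of 3+ cycles")
    sel = np.asarray(best)

    dt = 1.0 / trace.fs
    return CycleSet(
        onset_s=trace.t0 + onsets_a[sel] * dt,
        peak_s=trace.t0 + np.asarray(pk_list)[sel] * dt,
        end_s=trace.t0 + ends_a[sel] * dt,
    )


def flag_atypical(
    cycles: CycleSet,
    trace: RespirationTrace,
    n_points: int = 100,
    z_thresh: float = 3.0,
) -> CycleSet:
    """Flag cycles whose waveform is far from the centroid cycle.

    The whole trace is z-scored, each cycle's waveform is time-normalized to
    ``n_points`` samples, and the mean squared deviation from the pointwise
    mean (centroid) cycle is computed.  A cycle is atypical when its distance
    exceeds mean(distances) + ``z_thresh`` * SD(distances).  If all distances
    are identical (SD = 0), no cycle is flagged.
    """
    if cycles.n_cycles < 10:
        raise InsufficientDataError(
            f"{cycles.n_cycles} cycles; need >= 10 for a stable centroid"
        )
    x = trace.samples
    z = (x - x.mean()) / (x.std() or 1.0)
    t = trace.times

    grid = np.linspace(0.0, 1.0, n_points)
    wave = np.empty((cycles.n_cycles, n_points))
    n = z.size
    for i in range(cycles.n_cycles):
        lo = int(np.clip(round((cycles.onset_s[i] - trace.t0) * trace.fs), 0, n - 2))
        hi = int(np.clip(round((cycles.end_s[i] - trace.t0) * trace.fs), lo + 1, n - 1))
        seg = z[lo : hi + 1]
        wave[i] = np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg)

    centroid = wave.mean(axis=0)
    dist = ((wave - centroid) ** 2).mean(axis=1)
    sd = dist.std(ddof=1)
    if sd > 0:
        # the absolute floor (in squared z-units) keeps resampling round-off on
        # effectively identical cycles from registering as an outlier
        atypical = (dist > dist.mean() + z_thresh * sd) & (dist > 1e-3)
    else:
        atypical = np.zeros(cycles.n_cycles, dtype=bool)
    return CycleSet(
        onset_s=cycles.onset_s,
        peak_s=cycles.peak_s,
        end_s=cycles.end_s,
        distance=dist,
        atypical=atypical,
    )


def compute_phase(cycles: CycleSet, fs_out: float = 20.0,
                  t0: float | None = None, t_end: float | None = None) -> PhaseSeries:
    """Two-segment linear phase evaluated directly on the analysis grid.

    For a sample time t inside cycle (onset, peak, end):
    phase = pi * (t - onset) / (peak - onset) during inhalation and
    pi + pi * (t - peak) / (end - peak) during exhalation.  Samples outside
    any complete cycle, or inside an atypical one, are marked invalid.  No
    filtering or interpolation of wrapped values is involved.
    """
    if t0 is None:
        t0 = float(cycles.onset_s[0])
    if t_end is None:
        t_end = float(cycles.end_s[-1])
    n = int(np.floor((t_end - t0) * fs_out)) + 1
    t = t0 + np.arange(n) / fs_out

    idx = np.searchsorted(cycles.onset_s, t, side="right") - 1
    inside = (idx >= 0) & (idx < cycles.n_cycles)
    idx_c = np.clip(idx, 0, cycles.n_cycles - 1)
    inside &= t < cycles.end_s[idx_c]

    on = cycles.onset_s[idx_c]
    pk = cycles.peak_s[idx_c]
    end = cycles.end_s[idx_c]
    inhale = t < pk
    phase = np.where(
        inhale,
        np.pi * (t - on) / (pk - on),
        np.pi + np.pi * (t - pk) / (end - pk),
    )
    phase = np.mod(np.where(inside, phase, 0.0), TWO_PI)
    valid = inside & ~cycles.atypical[idx_c]
    return PhaseSeries(phase=phase, valid=valid, fs=fs_out, t0=t0)


def analytic_phase(trace: RespirationTrace, cutoff_hz: float = 2.0) -> np.ndarray:
    """Hilbert analytic-signal phase (radians in [0, 2*pi)), for cross-checks.

    The landmark-based two-segment phase is the primary definition; the
    analytic phase of the band-limited trace should co-rotate with it and is
    exposed for sanity checking only.
    """
    smooth = _smooth(trace, cutoff_hz)
    smooth = smooth - smooth.mean()
    return np.mod(np.angle(sps.hilbert(smooth)) + np.pi, TWO_PI)
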
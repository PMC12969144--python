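"""Trial-level plumbing: exclusion rules, epoching, cycle durations.

Trials are excluded when no response was registered within the deadline (where
one applies), when the reaction time falls outside [0.2, 3.0] s, or when the
respiratory cycle containing stimulus onset is atypical or missing.  Phase
epochs are sliced from the continuous 20 Hz phase series around each included
onset; cycle membership uses half-open intervals [inhale onset, exhale end) so
every time point belongs to exactly one cycle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CycleSet, EpochedPhase, PhaseSeries

# exclusion reasons in precedence order; each excluded trial carries exactly one
REASON_NO_COVERAGE = "no-coverage"
REASON_ATYPICAL = "atypical-cycle"
REASON_NO_RESPONSE = "no-response"
REASON_RT_SHORT = "rt-too-short"
REASON_RT_LONG = "rt-too-long"


def _cycle_index(onsets: np.ndarray, cycles: CycleSet) -> np.ndarray:
    idx = np.searchsorted(cycles.onset_s, onsets, side="right") - 1
    idx_c = np.clip(idx, 0, cycles.n_cycles - 1)
    covered = (idx >= 0) & (onsets < cycles.end_s[idx_c])
    return np.where(covered, idx_c, -1)


def filter_trials(
    table: pd.DataFrame,
    phase: PhaseSeries,
    cycles: CycleSet,
    rt_min_s: float = 0.2,
    rt_max_s: float = 3.0,
    deadline_required: bool = True,
) -> pd.DataFrame:
    """Apply the trial-exclusion rules; adds ``included`` and ``reason``.

    A trial is included iff its onset is covered by a typical respiratory
    cycle, a response was registered (when ``deadline_required``), and the RT
    lies in [rt_min_s, rt_max_s].  The first violated rule, in the order
    coverage -> atypicality -> response -> RT bounds, is recorded as the
    trial's single exclusion reason.
    """
    out = table.copy()
    onsets = out["onset_s"].to_numpy(dtype=float)
    idx = _cycle_index(onsets, cycles)

    n = len(out)
    reason = np.array([""] * n, dtype=object)
    span_ok = (idx >= 0) & (onsets >= phase.t0) & (
        onsets <= phase.t0 + (phase.n_samples - 1) / phase.fs
    )
    reason[~span_ok] = REASON_NO_COVERAGE

    atypical = np.zeros(n, dtype=bool)
    cov = span_ok
    atypical[cov] = cycles.atypical[idx[cov]]
    reason[(reason == "") & atypical] = REASON_ATYPICAL

    responded = out["responded"].to_numpy(dtype=bool) if "responded" in out else np.ones(n, bool)
    if deadline_required:
        reason[(reason == "") & ~responded] = REASON_NO_RESPONSE

    rt = out["rt_s"].to_numpy(dtype=float) if "rt_s" in out else np.full(n, np.nan)
    has_rt = np.isfinite(rt)
    reason[(reason == "") & has_rt & (rt < rt_min_s)] = REASON_RT_SHORT
    reason[(reason == "") & has_rt & (rt > rt_max_s)] = REASON_RT_LONG

    out["included"] = reason == ""
    out["reason"] = reason
    return out


def epoch_phase(
    phase: PhaseSeries,
    table: pd.DataFrame,
    window_s: tuple[float, float] = (-8.0, 4.0),
    included_only: bool = True,
) -> EpochedPhase:
    """Slice phase epochs around stimulus onsets.

    The default (-8, +4) s window at 20 Hz yields 241 samples per epoch.  Each
    onset is aligned to its nearest analysis-grid sample; cells falling outside
    the recording or inside atypical cycles are masked invalid.
    """
    lo, hi = window_s
    if hi <= lo:
        raise ValueError("window must satisfy start < end")
    rel_idx = np.arange(int(round(lo * phase.fs)), int(round(hi * phase.fs)) + 1)
    rel_times = rel_idx / phase.fs

    rows = table[table["included"]] if included_only and "included" in table else table
    onsets = rows["onset_s"].to_numpy(dtype=float)
    onset_idx = np.round((onsets - phase.t0) * phase.fs).astype(int)

    cells = onset_idx[:, None] + rel_idx[None, :]
    in_rec = (cells >= 0) & (cells < phase.n_samples)
    safe = np.clip(cells, 0, phase.n_samples - 1)
    ep = np.where(in_rec, phase.phase[safe], 0.0)
    ok = in_rec & phase.valid[safe]
    return EpochedPhase(phase=ep, valid=ok, rel_times=rel_times, fs=phase.fs)


def cycle_duration_at_onset(table: pd.DataFrame, cycles: CycleSet) -> pd.DataFrame:
    """Duration of the respiratory cycle containing each stimulus onset.

    Adds ``cycle_duration_s`` (NaN when the onset is not covered by any
    cycle).  Onsets exactly at a shared trough belong to the cycle starting
    there (half-open convention).
    """
    out = table.copy()
    idx = _cycle_index(out["onset_s"].to_numpy(dtype=float), cycles)
    dur = np.full(len(out), np.nan)
    cov = idx >= 0
    dur[cov] = cycles.durations[idx[cov]]
    out["cycle_duration_s"] = dur
    return out


def condition_means(table: pd.DataFrame, column: str,
                    included_only: bool = True) -> pd.Series:
    """Trial-averaged value of ``column`` per condition (one participant)."""
    rows = table[table["included"]] if included_only and "included" in table else table
    return rows.groupby("condition")[column].mean()
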
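"""Plain-text readers and writers for the pipeline's artifacts.

Respiration traces travel as two-column CSV (time_s, amplitude), trial tables
as TSV with a header, cycle sets as TSV, phase series as CSV, and epochs as a
TSV matrix with a JSON sidecar describing the time axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CycleSet, EpochedPhase, PhaseSeries, RespirationTrace


def write_trace(trace: RespirationTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "amplitude": trace.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace(path: str | Path, fs: float | None = None) -> RespirationTrace:
    """Read a trace CSV; single-column files need an explicit ``fs``."""
    df = pd.read_csv(path)
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        x = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError("trace file holds fewer than two samples")
        if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-6):
            raise ValueError("non-uniform sampling or gaps in trace file")
        return RespirationTrace(samples=x, fs=1.0 / float(np.mean(dt)), t0=float(t[0]))
    if fs is None:
        raise ValueError("single-column trace requires a sampling rate (fs)")
    return RespirationTrace(samples=df.iloc[:, 0].to_numpy(dtype=float), fs=fs)


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "onset_s" not in table.columns:
        raise ValueError("trial table must carry an onset_s column")
    return table


def write_cycles(cycles: CycleSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset_s": cycles.onset_s,
            "peak_s": cycles.peak_s,
            "end_s": cycles.end_s,
            "distance": cycles.distance,
            "atypical": cycles.atypical.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_phase(phase: PhaseSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": phase.times,
            "phase_rad": phase.phase,
            "valid": phase.valid.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_epochs(epochs: EpochedPhase, basepath: str | Path) -> None:
    """Write the epoch matrix plus a JSON sidecar with the time axis."""
    base = Path(basepath)
    np.savetxt(base.with_suffix(".phase.tsv"), epochs.phase, delimiter="\t", fmt="%.6f")
    np.savetxt(base.with_suffix(".valid.tsv"), epochs.valid.astype(int),
               delimiter="\t", fmt="%d")
    sidecar = {
        "fs": epochs.fs,
        "window_s": [float(epochs.rel_times[0]), float(epochs.rel_times[-1])],
        "n_trials": int(epochs.n_trials),
        "n_times": int(epochs.n_times),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_epochs(basepath: str | Path) -> EpochedPhase:
    base = Path(basepath)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    phase = np.loadtxt(base.with_suffix(".phase.tsv"), delimiter="\t", ndmin=2)
    valid = np.loadtxt(base.with_suffix(".valid.tsv"), delimiter="\t", ndmin=2)
    lo, hi = sidecar["window_s"]
    rel = np.linspace(lo, hi, sidecar["n_times"])
    return EpochedPhase(phase=phase, valid=valid.astype(bool), rel_times=rel,
                        fs=sidecar["fs"])
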
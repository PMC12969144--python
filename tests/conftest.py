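"""Shared fixtures: small simulated recordings reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from respalign.preprocess import compute_phase, flag_atypical, segment_cycles
from respalign.synthetic import CouplingSpec, ParadigmSpec, gen_respiration, gen_schedule
from respalign.types import CycleSet, RespirationTrace


@pytest.fixture(scope="session")
def coupled_recording():
    """Moderately coupled experiment-1 recording with generator ground truth."""
    schedule = gen_schedule(ParadigmSpec.for_experiment(1, 300), seed=21)
    coupling = CouplingSpec(kappa_by_condition={"LONG": 1.0, "SHORT": 1.0},
                            cycle_mean_s=3.8)
    trace, truth = gen_respiration(schedule, coupling, fs=100.0, seed=21,
                                   return_truth=True)
    return schedule, coupling, trace, truth


@pytest.fixture(scope="session")
def uncoupled_recording():
    """Free-running (kappa = 0) recording: cycle statistics are undisturbed."""
    schedule = gen_schedule(ParadigmSpec.for_experiment(1, 400), seed=8)
    coupling = CouplingSpec(kappa_by_condition={"LONG": 0.0, "SHORT": 0.0},
                            cycle_mean_s=3.8)
    trace, truth = gen_respiration(schedule, coupling, fs=100.0, seed=8,
                                   return_truth=True)
    return schedule, coupling, trace, truth


@pytest.fixture(scope="session")
def segmented(coupled_recording):
    schedule, coupling, trace, truth = coupled_recording
    cycles = flag_atypical(segment_cycles(trace), trace)
    phase = compute_phase(cycles, fs_out=20.0, t0=trace.t0,
                          t_end=trace.t0 + trace.duration)
    return schedule, trace, truth, cycles, phase


def uniform_cycle_set(n_cycles: int = 20, duration: float = 4.0,
                      inhale: float = 2.0) -> CycleSet:
    """Hand-built tiling cycles for unit tests (onset at k*duration)."""
    onsets = np.arange(n_cycles) * duration
    return CycleSet(onset_s=onsets, peak_s=onsets + inhale,
                    end_s=onsets + duration)


def synthetic_cycle_trace(amplitudes, duration: float = 4.0, fs: float = 50.0,
                          inhale_frac: float = 0.5) -> tuple[RespirationTrace, CycleSet]:
    """Concatenated half-cosine cycles with per-cycle amplitudes and exact landmarks."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = amplitudes.size
    t = np.arange(int(n * duration * fs)) / fs
    idx = np.minimum((t // duration).astype(int), n - 1)
    rel = t - idx * duration
    ti = inhale_frac * duration
    phase = np.where(rel < ti, np.pi * rel / ti,
                     np.pi + np.pi * (rel - ti) / (duration - ti))
    samples = -np.cos(phase) * amplitudes[idx]
    trace = RespirationTrace(samples=samples, fs=fs)
    onsets = np.arange(n) * duration
    cycles = CycleSet(onset_s=onsets, peak_s=onsets + ti, end_s=onsets + duration)
    return trace, cycles
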
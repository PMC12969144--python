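"""Synthetic task paradigms, respiration traces, and behavior.

Emulates three visual-discrimination experiments in which respiration was
recorded while trial demands were manipulated:

* experiment 1 — blocked LONG vs SHORT response deadlines; fixed 1.0 s
  pre-stimulus fixation, inter-trial intervals uniform in [3.5, 4.0] s;
* experiments 2 and 3 — trial-wise high vs low value (experiment 3 yokes value
  to difficulty); a 3 s countdown cue, inter-trial intervals uniform in
  [1.7, 2.8] s, high:low value ratio 1:2.33.

Respiration is generated as a chain of half-cosine cycles whose timing is
locally adjusted before each predicted stimulus onset so that the respiratory
phase at onset follows a von Mises distribution with a per-condition
concentration kappa.  kappa = 0 reproduces the uncoupled (uniform-phase) limit;
the expected phase-locking vector strength at onset is the Bessel ratio
I1(kappa)/I0(kappa), which makes the generator analytically checkable.

The adjustment mechanism (stretching or shrinking the cycles that precede an
onset) is a modelling convenience, not a claim about respiratory physiology:
the experiments observe alignment but do not identify how it arises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import RespirationTrace, TWO_PI

# substream tags so one master seed fans out to independent generators
_STREAM_SCHEDULE = 1
_STREAM_RESPIRATION = 2
_STREAM_BEHAVIOR = 3


def rng_for(seed: int, *keys: int) -> np.random.Generator:
    """Independent substream keyed by (seed, *keys).

    Randomization draws are keyed by content (participant, procedure), never by
    execution order, so parallel and serial runs agree bit for bit.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass
class ParadigmSpec:
    """Timing and condition scheme of one experiment.

    ``response_window_s`` is the fixed stimulus + response epoch appended after
    each onset; together with the pre-stimulus period and the ITI draw it sets
    the onset-to-onset interval (about 5.75 s for experiment 1 and 7.4-7.6 s
    for experiments 2-3).
    """

    experiment_id: int
    n_trials: int
    pre_stimulus_s: float
    iti_range_s: tuple[float, float]
    response_window_s: float
    value_ratio: float = 2.33  # low-value trials per high-value trial
    lead_in_s: float = 12.0

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3):
            raise ValueError("experiment_id must be 1, 2 or 3")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        lo, hi = self.iti_range_s
        if lo > hi:
            raise ValueError("iti_range_s must satisfy low <= high")

    @classmethod
    def for_experiment(cls, experiment_id: int, n_trials: int | None = None) -> "ParadigmSpec":
        if experiment_id == 1:
            return cls(1, 800 if n_trials is None else n_trials, pre_stimulus_s=1.0,
                       iti_range_s=(3.5, 4.0), response_window_s=1.0)
        if experiment_id == 2:
            return cls(2, 660 if n_trials is None else n_trials, pre_stimulus_s=3.0,
                       iti_range_s=(1.7, 2.8), response_window_s=2.33)
        if experiment_id == 3:
            return cls(3, 630 if n_trials is None else n_trials, pre_stimulus_s=3.0,
                       iti_range_s=(1.7, 2.8), response_window_s=2.17)
        raise ValueError("experiment_id must be 1, 2 or 3")


@dataclass
class CouplingSpec:
    """How tightly respiration aligns to predicted stimulus onsets.

    mu is the preferred phase at onset (defaults to peak inhalation, pi);
    kappa_by_condition maps each condition label to a von Mises concentration.
    Cycle durations are lognormal with mean ``cycle_mean_s`` and coefficient of
    variation ``cycle_cv``; ``inhale_fraction`` splits each cycle into the
    rising (inhale) and falling (exhale) half-cosine segments.
    """

    mu: float = np.pi
    kappa_by_condition: dict[str, float] = field(default_factory=lambda: {"SHORT": 3.0, "LONG": 1.0})
    cycle_mean_s: float = 3.8
    cycle_cv: float = 0.12
    inhale_fraction: float = 0.45
    amp_cv: float = 0.08
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.kappa_by_condition.values()):
            raise ValueError("kappa must be >= 0")
        if self.cycle_mean_s <= 0:
            raise ValueError("cycle_mean_s must be positive")
        if not 0 < self.inhale_fraction < 1:
            raise ValueError("inhale_fraction must be in (0, 1)")

    def kappa_for(self, condition: str) -> float:
        if condition in self.kappa_by_condition:
            return self.kappa_by_condition[condition]
        if None in self.kappa_by_condition:  # type: ignore[comparison-overlap]
            return self.kappa_by_condition[None]  # type: ignore[index]
        raise KeyError(f"no kappa for condition {condition!r}")

    @classmethod
    def for_experiment(cls, experiment_id: int) -> "CouplingSpec":
        if experiment_id == 1:
            return cls(kappa_by_condition={"SHORT": 3.0, "LONG": 1.0}, cycle_mean_s=3.79)
        if experiment_id == 2:
            return cls(kappa_by_condition={"high": 1.0, "low": 1.0}, cycle_mean_s=4.23)
        if experiment_id == 3:
            return cls(kappa_by_condition={"high": 3.0, "low": 1.0}, cycle_mean_s=3.55)
        raise ValueError("experiment_id must be 1, 2 or 3")


@dataclass
class BehaviorSpec:
    """Shifted-lognormal reaction times plus Bernoulli accuracy and misses.

    rt = rt_location_s[c] + Lognormal(log(rt_scale[c]), rt_sigma); the mean RT
    per condition is therefore location + scale * exp(rt_sigma**2 / 2).
    """

    rt_location_s: dict[str, float]
    rt_scale: dict[str, float]
    accuracy_prob: dict[str, float]
    miss_prob: dict[str, float]
    rt_sigma: float = 0.4

    def __post_init__(self) -> None:
        for name, probs in (("accuracy_prob", self.accuracy_prob), ("miss_prob", self.miss_prob)):
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if any(v < 0 for v in self.rt_location_s.values()):
            raise ValueError("rt_location_s must be >= 0")

    def mean_rt(self, condition: str) -> float:
        return self.rt_location_s[condition] + self.rt_scale[condition] * float(
            np.exp(self.rt_sigma**2 / 2.0)
        )

    @classmethod
    def for_experiment(cls, experiment_id: int) -> "BehaviorSpec":
        if experiment_id == 1:
            # SHORT-deadline responses are faster, less accurate, missed more
            return cls(
                rt_location_s={"SHORT": 0.31, "LONG": 0.47},
                rt_scale={"SHORT": 0.14, "LONG": 0.14},
                accuracy_prob={"SHORT": 0.907, "LONG": 0.968},
                miss_prob={"SHORT": 0.08, "LONG": 0.01},
            )
        if experiment_id == 2:
            return cls(
                rt_location_s={"high": 1.10, "low": 1.08},
                rt_scale={"high": 0.14, "low": 0.14},
                accuracy_prob={"high": 0.805, "low": 0.800},
                miss_prob={"high": 0.02, "low": 0.02},
            )
        if experiment_id == 3:
            return cls(
                rt_location_s={"high": 1.01, "low": 0.99},
                rt_scale={"high": 0.14, "low": 0.14},
                accuracy_prob={"high": 0.743, "low": 0.757},
                miss_prob={"high": 0.02, "low": 0.02},
            )
        raise ValueError("experiment_id must be 1, 2 or 3")


def gen_schedule(spec: ParadigmSpec, seed: int) -> pd.DataFrame:
    """Trial schedule: strictly increasing onsets and condition labels.

    Experiment 1 presents LONG blocks first, then SHORT, mirroring the
    block-wise deadline manipulation; experiments 2-3 assign high/low value
    trial-wise by a seeded permutation (unpredictable from trial history) with
    the configured high:low ratio.  Experiment 2 additionally carries an
    independent easy/hard difficulty label; experiment 3 yokes difficulty to
    value.
    """
    rng = rng_for(seed, _STREAM_SCHEDULE)
    n = spec.n_trials
    itis = rng.uniform(*spec.iti_range_s, size=n)
    # cursor walks ITI -> fixed pre-stimulus cue -> onset -> response epoch
    onsets = np.empty(n)
    t = spec.lead_in_s
    for i in range(n):
        t += itis[i] + spec.pre_stimulus_s
        onsets[i] = t
        t += spec.response_window_s

    if spec.experiment_id == 1:
        condition = np.array(["LONG"] * (n - n // 2) + ["SHORT"] * (n // 2))
        difficulty = np.array([""] * n)
    else:
        n_high = int(round(n / (1.0 + spec.value_ratio)))
        condition = np.array(["high"] * n_high + ["low"] * (n - n_high))
        rng.shuffle(condition)
        if spec.experiment_id == 2:
            difficulty = np.where(rng.random(n) < 0.5, "hard", "easy")
        else:
            difficulty = np.where(condition == "high", "hard", "easy")

    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "onset_s": onsets,
            "condition": condition,
            "difficulty": difficulty,
            "iti_s": itis,
            "pre_stimulus_s": np.full(n, spec.pre_stimulus_s),
        }
    )


def _phase_to_offset(phi: np.ndarray | float, dur: float, f: float) -> float:
    """Time into a cycle of duration ``dur`` at which the phase equals phi."""
    t_inhale = f * dur
    if phi < np.pi:
        return float(t_inhale * phi / np.pi)
    return float(t_inhale + (1.0 - f) * dur * (phi - np.pi) / np.pi)


def _offset_fraction(phi: float, f: float) -> float:
    """Fraction of a cycle elapsed when the phase equals phi (any duration)."""
    if phi < np.pi:
        return f * phi / np.pi
    return f + (1.0 - f) * (phi - np.pi) / np.pi


def piecewise_phase(t: np.ndarray, starts: np.ndarray, durs: np.ndarray,
                    inhale_fraction: float) -> np.ndarray:
    """Two-segment linear phase of the cycle chain evaluated at times ``t``.

    0 -> pi over the inhale segment, pi -> 2*pi over the exhale segment; times
    outside the chain are clamped to the nearest cycle edge.
    """
    t = np.asarray(t, dtype=float)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, starts.size - 1)
    rel = np.clip(t - starts[idx], 0.0, None)
    d = durs[idx]
    ti = inhale_fraction * d
    inhale = rel < ti
    phase = np.where(
        inhale,
        np.pi * rel / ti,
        np.pi + np.pi * (rel - ti) / ((1.0 - inhale_fraction) * d),
    )
    return np.mod(phase, TWO_PI)


@dataclass
class RespirationTruth:
    """Generator-side ground truth for validating the analysis chain."""

    cycle_starts: np.ndarray
    cycle_durations: np.ndarray
    phase_at_onset: np.ndarray
    inhale_fraction: float

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        return piecewise_phase(t, self.cycle_starts, self.cycle_durations,
                               self.inhale_fraction)


def gen_respiration(
    schedule: pd.DataFrame,
    coupling: CouplingSpec,
    fs: float = 1000.0,
    seed: int = 0,
    tail_s: float = 12.0,
    return_truth: bool = False,
) -> RespirationTrace | tuple[RespirationTrace, RespirationTruth]:
    """Respiration trace whose phase at each stimulus onset is von Mises.

    For each scheduled onset a target phase is drawn from
    von Mises(mu, kappa_condition); the cycle containing the onset is then
    placed (its start and duration solved, within bounds, from the target
    phase) and the gap back to the previously laid cycle is bridged with
    ordinary lognormal-duration cycles.  The resulting chain is rendered as
    -cos(phase) with mild per-cycle amplitude variation and additive noise, so
    troughs mark inspiration onsets and peaks mark peak inhalation.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must contain at least one trial")
    if fs < 100.0:
        raise ValueError("fs must be >= 100 Hz to resolve cycle landmarks")

    rng = rng_for(seed, _STREAM_RESPIRATION)
    mean = coupling.cycle_mean_s
    f = coupling.inhale_fraction
    sigma = float(np.sqrt(np.log(1.0 + coupling.cycle_cv**2)))
    mu_ln = float(np.log(mean) - sigma**2 / 2.0)
    d_lo, d_hi = 0.47 * mean, 1.9 * mean

    def draw_durations(k: int) -> np.ndarray:
        return np.clip(rng.lognormal(mu_ln, sigma, size=k), d_lo, d_hi)

    starts: list[float] = []
    durs: list[float] = []
    is_filler: list[bool] = []
    t_cur = 0.0

    onsets_arr = schedule["onset_s"].to_numpy(dtype=float)
    conds_arr = schedule["condition"].to_numpy()
    for i, (onset, cond) in enumerate(zip(onsets_arr, conds_arr)):
        next_onset = onsets_arr[i + 1] if i + 1 < onsets_arr.size else np.inf
        kappa = coupling.kappa_for(str(cond))
        if kappa < 1e-12:
            # uncoupled limit: respiration free-runs past this onset and the
            # phase at onset is uniform by construction
            continue
        phi = float(np.mod(rng.vonmises(coupling.mu, kappa), TWO_PI))
        phi = float(np.clip(phi, 1e-4, TWO_PI - 1e-4))

        if onset <= t_cur:
            # onset falls inside an already-laid cycle (rare, short intervals):
            # the realized phase is whatever that cycle dictates
            continue

        # bridge t_cur -> onset with k filler cycles plus the leading
        # c-fraction of the onset cycle, sharing a common rescaling so the
        # drawn phase lands exactly on the onset.  Cycle durations are kept
        # inside [0.47, 2.4] x cycle_mean_s, and the onset cycle may never
        # extend past the next onset (whose phase would then be
        # uncontrolled); when these bounds bind, the phase at onset deviates
        # slightly from the draw (the adjustment is bounded by design).
        c = _offset_fraction(phi, f)
        d_draw = float(draw_durations(1)[0])
        span = onset - t_cur
        k = max(0, int(round(span / mean - c)))
        if k > 0:
            fillers = draw_durations(k)
            scale = span / (fillers.sum() + c * d_draw)
            cap = (next_onset - onset - 0.3 * mean) / max(1.0 - c, 1e-6)
            d_star = float(np.clip(d_draw * scale, d_lo, min(d_hi, max(cap, d_lo))))
            fillers = fillers * ((span - c * d_star) / fillers.sum())
            c_real = c
            for d in fillers:
                starts.append(t_cur)
                durs.append(float(d))
                is_filler.append(True)
                t_cur += float(d)
        else:
            cap0 = next_onset - 0.3 * mean - t_cur
            d_star = float(np.clip(span / c, d_lo, min(d_hi, max(cap0, d_lo))))
            c_real = span / d_star
        s_star = onset - c_real * d_star
        starts.append(s_star)
        durs.append(float(d_star))
        is_filler.append(False)
        t_cur = s_star + d_star

    total = float(schedule["onset_s"].iloc[-1]) + tail_s
    while t_cur < total:
        d = float(draw_durations(1)[0])
        starts.append(t_cur)
        durs.append(d)
        is_filler.append(True)
        t_cur += d

    starts_a = np.asarray(starts)
    durs_a = np.asarray(durs)

    t = np.arange(int(np.ceil(t_cur * fs))) / fs
    phase = piecewise_phase(t, starts_a, durs_a, f)
    amps = np.clip(rng.normal(1.0, coupling.amp_cv, size=starts_a.size), 0.5, None)
    idx = np.clip(np.searchsorted(starts_a, t, side="right") - 1, 0, starts_a.size - 1)
    # amplitude varies per cycle through an envelope that equals 1 at every
    # trough, keeping the waveform continuous at cycle boundaries
    envelope = 1.0 + (amps[idx] - 1.0) * np.sin(phase / 2.0) ** 2
    samples = -np.cos(phase) * envelope
    if coupling.noise_sd > 0:
        samples = samples + coupling.noise_sd * rng.standard_normal(t.size)

    trace = RespirationTrace(samples=samples, fs=fs, t0=0.0)
    if not return_truth:
        return trace
    truth = RespirationTruth(
        cycle_starts=starts_a,
        cycle_durations=durs_a,
        phase_at_onset=piecewise_phase(schedule["onset_s"].to_numpy(),
                                       starts_a, durs_a, f),
        inhale_fraction=f,
    )
    return trace, truth


def gen_behavior(schedule: pd.DataFrame, spec: BehaviorSpec, seed: int) -> pd.DataFrame:
    """Fill rt_s, correct and responded columns of a schedule.

    Misses (no response within the deadline) get rt_s = NaN and correct =
    False; RTs follow the shifted-lognormal model per condition.
    """
    rng = rng_for(seed, _STREAM_BEHAVIOR)
    out = schedule.copy()
    conds = out["condition"].to_numpy()
    unknown = set(conds) - set(spec.rt_location_s)
    if unknown:
        raise ValueError(f"conditions {sorted(unknown)} not covered by BehaviorSpec")

    n = len(out)
    loc = np.array([spec.rt_location_s[c] for c in conds])
    scale = np.array([spec.rt_scale[c] for c in conds])
    p_acc = np.array([spec.accuracy_prob[c] for c in conds])
    p_miss = np.array([spec.miss_prob[c] for c in conds])

    responded = rng.random(n) >= p_miss
    rt = loc + scale * np.exp(spec.rt_sigma * rng.standard_normal(n))
    rt[~responded] = np.nan
    correct = (rng.random(n) < p_acc) & responded

    out["rt_s"] = rt
    out["correct"] = correct
    out["responded"] = responded
    return out


def simulate_participant(
    experiment_id: int,
    seed: int,
    n_trials: int | None = None,
    coupling: CouplingSpec | None = None,
    behavior: BehaviorSpec | None = None,
    paradigm: ParadigmSpec | None = None,
    fs: float = 1000.0,
    return_truth: bool = False,
):
    """One participant's schedule, behavior, and respiration trace."""
    paradigm = paradigm or ParadigmSpec.for_experiment(experiment_id, n_trials)
    coupling = coupling or CouplingSpec.for_experiment(experiment_id)
    behavior = behavior or BehaviorSpec.for_experiment(experiment_id)
    schedule = gen_schedule(paradigm, seed)
    table = gen_behavior(schedule, behavior, seed)
    resp = gen_respiration(table, coupling, fs=fs, seed=seed, return_truth=return_truth)
    if return_truth:
        trace, truth = resp
        return table, trace, truth
    return table, resp
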
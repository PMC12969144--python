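"""Generator tests: schedules, phase coupling law, behavior model."""

from __future__ import annotations

import numpy as np
import pingouin as pg
import pytest
from scipy import special, stats

from respalign.synthetic import (
    BehaviorSpec,
    CouplingSpec,
    ParadigmSpec,
    gen_behavior,
    gen_respiration,
    gen_schedule,
)


class TestSchedule:
    def test_experiment1_timing_structure(self):
        """Fixed 1 s pre-stimulus, ITIs uniform in [3.5, 4.0] s, onsets increasing."""
        spec = ParadigmSpec.for_experiment(1, 200)
        table = gen_schedule(spec, seed=0)
        assert (table["pre_stimulus_s"] == 1.0).all()
        assert table["iti_s"].between(3.5, 4.0).all()
        onsets = table["onset_s"].to_numpy()
        assert (np.diff(onsets) > 0).all()
        # onset-to-onset = ITI + pre-stimulus + stimulus/response epoch
        expected = table["iti_s"].to_numpy()[1:] + 1.0 + spec.response_window_s
        np.testing.assert_allclose(np.diff(onsets), expected, atol=1e-9)

    def test_experiment1_blocked_conditions(self):
        table = gen_schedule(ParadigmSpec.for_experiment(1, 100), seed=3)
        assert (table["condition"][:50] == "LONG").all()
        assert (table["condition"][50:] == "SHORT").all()

    def test_single_trial_and_invalid_spec(self):
        table = gen_schedule(ParadigmSpec.for_experiment(1, 1), seed=1)
        assert len(table) == 1
        assert table["onset_s"].iloc[0] > 0
        with pytest.raises(ValueError):
            ParadigmSpec.for_experiment(1, 0)

    def test_value_ratio_experiment2(self):
        """high:low = 1:2.33 gives a high-value fraction near 1/3.33 = 0.3003."""
        table = gen_schedule(ParadigmSpec.for_experiment(2, 10000), seed=5)
        frac_high = (table["condition"] == "high").mean()
        se = np.sqrt(0.3003 * 0.6997 / 10000)
        assert abs(frac_high - 1.0 / 3.33) <= 3 * se + 1.0 / 10000

    def test_experiment3_difficulty_yoked_to_value(self):
        table = gen_schedule(ParadigmSpec.for_experiment(3, 300), seed=2)
        assert ((table["condition"] == "high") == (table["difficulty"] == "hard")).all()

    def test_schedule_conservation(self):
        table = gen_schedule(ParadigmSpec.for_experiment(2, 333), seed=9)
        assert len(table) == 333
        assert set(table["condition"]) == {"high", "low"}


class TestRespirationCoupling:
    def test_determinism_bit_identical(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 40), seed=4)
        coup = CouplingSpec()
        a = gen_respiration(sched, coup, fs=100.0, seed=11)
        b = gen_respiration(sched, coup, fs=100.0, seed=11)
        c = gen_respiration(sched, coup, fs=100.0, seed=12)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_uncoupled_phase_is_uniform(self, uncoupled_recording):
        """kappa = 0: a Rayleigh test must not reject circular uniformity."""
        schedule, _, _, truth = uncoupled_recording
        z, p = pg.circ_rayleigh(truth.phase_at_onset)
        assert p > 0.01

    def test_preferred_phase_recovered(self):
        """kappa = 4, mu = pi: circular mean of onset phases within 0.15 rad of pi."""
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 400), seed=6)
        coup = CouplingSpec(kappa_by_condition={"LONG": 4.0, "SHORT": 4.0})
        _, truth = gen_respiration(sched, coup, fs=100.0, seed=6, return_truth=True)
        mean = np.angle(np.exp(1j * truth.phase_at_onset).mean())
        assert abs(np.angle(np.exp(1j * (mean - np.pi)))) <= 0.15

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0, 4.0])
    def test_bessel_ratio_law(self, kappa):
        """plvs of onset phases converges to I1(kappa)/I0(kappa).

        The Monte-Carlo SE oracle is estimated from independent von Mises
        samples of the same size.
        """
        n = 400
        sched = gen_schedule(ParadigmSpec.for_experiment(1, n), seed=13)
        coup = CouplingSpec(kappa_by_condition={"LONG": kappa, "SHORT": kappa})
        _, truth = gen_respiration(sched, coup, fs=100.0, seed=13, return_truth=True)
        observed = np.abs(np.exp(1j * truth.phase_at_onset).mean())

        expected = special.i1(kappa) / special.i0(kappa) if kappa > 0 else 0.0
        rng = np.random.default_rng(1000 + int(kappa * 10))
        reps = np.abs(np.exp(1j * rng.vonmises(np.pi, max(kappa, 1e-12),
                                               size=(200, n))).mean(axis=1))
        mc_se = reps.std(ddof=1)
        mc_mean_bias = reps.mean() - expected  # finite-n resultant bias (kappa=0)
        assert abs(observed - expected - mc_mean_bias) <= 3 * mc_se

    def test_waveform_has_no_flat_segments(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 20), seed=2)
        coup = CouplingSpec(noise_sd=0.0)
        trace = gen_respiration(sched, coup, fs=100.0, seed=2)
        d = np.diff(trace.samples)
        flat = d == 0.0
        assert not (flat[:-1] & flat[1:]).any()

    def test_low_sampling_rate_rejected(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 5), seed=0)
        with pytest.raises(ValueError):
            gen_respiration(sched, CouplingSpec(), fs=50.0, seed=0)

    def test_empty_schedule_rejected(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 5), seed=0).iloc[:0]
        with pytest.raises(ValueError):
            gen_respiration(sched, CouplingSpec(), fs=100.0, seed=0)


class TestBehavior:
    def _spec(self, **overrides):
        base = dict(
            rt_location_s={"SHORT": 0.46, "LONG": 0.62},
            rt_scale={"SHORT": 0.14, "LONG": 0.14},
            accuracy_prob={"SHORT": 0.9, "LONG": 0.95},
            miss_prob={"SHORT": 0.0, "LONG": 0.0},
        )
        base.update(overrides)
        return BehaviorSpec(**base)

    def test_no_misses_means_all_responses(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 200), seed=1)
        table = gen_behavior(sched, self._spec(), seed=1)
        assert table["responded"].all()

    def test_perfect_accuracy(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 200), seed=1)
        spec = self._spec(accuracy_prob={"SHORT": 1.0, "LONG": 1.0})
        table = gen_behavior(sched, spec, seed=1)
        assert table["correct"].all()

    def test_rt_means_match_shifted_lognormal(self):
        """Sample mean RT = location + scale*exp(sigma^2/2) within 0.02 s."""
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 4000), seed=7)
        spec = self._spec()
        table = gen_behavior(sched, spec, seed=7)
        for cond in ("SHORT", "LONG"):
            sample = table.loc[table["condition"] == cond, "rt_s"].mean()
            assert abs(sample - spec.mean_rt(cond)) <= 0.02

    def test_miss_probability_respected(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(1, 4000), seed=3)
        spec = self._spec(miss_prob={"SHORT": 0.2, "LONG": 0.0})
        table = gen_behavior(sched, spec, seed=3)
        short = table[table["condition"] == "SHORT"]
        miss_rate = 1.0 - short["responded"].mean()
        assert abs(miss_rate - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / len(short))
        assert table.loc[~table["responded"], "rt_s"].isna().all()

    def test_unknown_condition_rejected(self):
        sched = gen_schedule(ParadigmSpec.for_experiment(2, 50), seed=2)
        with pytest.raises(ValueError):
            gen_behavior(sched, self._spec(), seed=2)  # spec lacks high/low

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            self._spec(accuracy_prob={"SHORT": 1.4, "LONG": 0.9})
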
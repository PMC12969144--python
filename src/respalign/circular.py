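"""Circular statistics for trial-averaged respiratory phase and behavior links.

Per participant and condition the trial-averaged respiratory phase at stimulus
onset is summarized by its circular mean and resultant length; condition
differences in these angles are tested with a sign-flip randomization test and
summarized with a percentile bootstrap confidence interval.  Cycle-duration
contrasts reuse the paired t machinery and behavioral links use Spearman rank
correlations of participant-wise condition differences.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .alignment import paired_t
from .types import AngularTestResult, InsufficientDataError, PairedTResult, TWO_PI


def circ_mean(phases: np.ndarray) -> tuple[float, float]:
    """Circular mean angle and resultant length of a set of angles.

    mean_angle = arg sum_j exp(i*phi_j); resultant = |sum_j exp(i*phi_j)| / n.
    A vanishing resultant leaves the mean undefined (NaN).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one angle")
    z = np.exp(1j * phases).mean()
    r = float(np.abs(z))
    if r < 1e-12:
        return float("nan"), 0.0
    return float(np.mod(np.angle(z), TWO_PI)), r


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    return -np.mod(-np.asarray(a) + np.pi, TWO_PI) + np.pi


def _circ_mean_signed(angles: np.ndarray) -> float:
    """Circular mean reported in (-pi, pi] (for difference statistics)."""
    z = np.exp(1j * np.asarray(angles, dtype=float)).mean()
    return float(np.angle(z))


def angular_difference_test(
    angles_a: np.ndarray,
    angles_b: np.ndarray,
    n_rand: int = 4000,
    conf: float = 0.95,
    seed: int | None = None,
    exhaustive: bool = False,
    ci_method: str = "bootstrap",
) -> AngularTestResult:
    """Randomization test comparing paired mean angles between conditions.

    The reported estimate is the circular mean of the per-participant wrapped
    angle differences a_i - b_i.  The null flips each participant's difference
    sign independently (``n_rand`` draws, or all 2^n patterns when
    ``exhaustive``).  Sign flips leave every cos(d_i) unchanged and negate
    sin(d_i), so the test reduces exactly to a sign-flip test on the sine
    components; this is equivalent to comparing the mean angles whenever the
    cosine sum is positive and stays well defined when the angle would
    degenerate.  The CI is a percentile bootstrap over participants of the
    circular-mean difference (``ci_method='randomization'`` uses the
    percentiles of the sign-flip distribution of the mean angle instead).
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired angle vectors required")
    n = a.size
    if n < 3:
        raise InsufficientDataError("need >= 3 participants")
    d = np.asarray(wrap_angle(a - b), dtype=float)
    observed = _circ_mean_signed(d)

    rng = np.random.default_rng(seed)
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to <= 20 participants")
        R = 2**n
        bits = (np.arange(R)[:, None] >> np.arange(n)[None, :]) & 1
        signs = np.where(bits == 1, 1.0, -1.0)
    else:
        R = n_rand
        signs = rng.choice([-1.0, 1.0], size=(R, n))
    sin_obs = float(np.sin(d).mean())
    null_sin = signs @ np.sin(d) / n
    exceed = (np.abs(null_sin) >= abs(sin_obs) - 1e-12).sum()
    if exhaustive:
        p = float(exceed) / R
    else:
        p = (1.0 + float(exceed)) / (1.0 + R)
    null_stats = np.angle(np.cos(d).mean() + 1j * null_sin)

    if ci_method == "bootstrap":
        idx = rng.integers(0, n, size=(n_rand, n))
        boot = np.angle(np.exp(1j * d[idx]).mean(axis=1))
        # center percentiles on the observed direction to avoid wrap artifacts
        boot = observed + np.asarray(wrap_angle(boot - observed), dtype=float)
        lo, hi = np.quantile(boot, [(1 - conf) / 2, 1 - (1 - conf) / 2])
    elif ci_method == "randomization":
        lo, hi = np.quantile(null_stats, [(1 - conf) / 2, 1 - (1 - conf) / 2])
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'randomization'")

    return AngularTestResult(
        mean_diff_rad=float(observed),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_rand=R,
        conf=conf,
        seed=seed,
    )


def duration_contrast(durations_a: np.ndarray, durations_b: np.ndarray) -> PairedTResult:
    """Paired t-test of per-participant trial-mean cycle durations."""
    return paired_t(durations_a, durations_b)


def diff_correlation(x_diff: np.ndarray, y_diff: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of participant-wise condition differences.

    Tie-adjusted ranks, two-sided p.  A constant vector leaves the correlation
    undefined (NaN, NaN).
    """
    x = np.asarray(x_diff, dtype=float)
    y = np.asarray(y_diff, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors required")
    if x.size < 5:
        raise InsufficientDataError("need >= 5 participants")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def polar_histogram(angles: np.ndarray, path=None, n_bins: int = 24, ax=None):
    """Polar histogram of angles (one spoke per participant summary).

    Mirrors the angular-histogram panels of the condition-difference figures;
    saves vector graphics when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    angles = np.mod(np.asarray(angles, dtype=float), TWO_PI)
    created = ax is None
    if created:
        fig = plt.figure(figsize=(4, 4))
        ax = fig.add_subplot(111, projection="polar")
    edges = np.linspace(0, TWO_PI, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    ax.bar((edges[:-1] + edges[1:]) / 2, counts, width=np.diff(edges),
           alpha=0.7, edgecolor="k")
    mean, r = circ_mean(angles)
    if np.isfinite(mean):
        ax.annotate("", xy=(mean, r * counts.max()), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="-|>", color="crimson", lw=2))
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
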
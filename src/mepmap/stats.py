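"""Effect sizes, within-participant tests, effect combination, and power.

Within-participant designs are analysed with one-sample/paired t tests on
the per-participant contrasts, summarised by Cohen's d_z = mean / SD of
the differences.  Independent effects are combined by fixed-effect
inverse-variance weighting with Var(d) ~ 1/n + d^2 / (2n); required
sample sizes for a paired design use the normal approximation

    n = ceil(((z_{1-alpha/tails} + z_{power}) / d)^2),

with an exact noncentral-t alternative that is never smaller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectRecord",
    "paired_t",
    "combine_effects",
    "sample_size",
    "rmt_effect_correlation",
    "proportion_pct",
]


@dataclass(frozen=True)
class EffectRecord:
    """One experiment's within-participant effect."""

    label: str
    n: int
    cohens_d: float
    t: float | None = None
    df: int | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")


def paired_t(diffs) -> tuple[float, int, float, float]:
    """One-sample t on within-participant differences.

    Returns (t, df, two-tailed p, Cohen's d_z).  Zero-variance differences
    are a signalled error (the statistic is undefined).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need n >= 2 differences")
    sd = d.std(ddof=1)
    if np.allclose(sd, 0.0):
        raise ValueError("zero-variance differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), float(d.mean() / sd)


def combine_effects(records: list[EffectRecord], method: str = "fixed_inverse_variance") -> float:
    """Combine Cohen's d across experiments.

    ``fixed_inverse_variance`` weights each d by 1/Var(d) with
    Var(d) ~ 1/n + d^2/(2n); ``unweighted`` is the plain mean.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 effect records")
    d = np.array([r.cohens_d for r in records], dtype=float)
    n = np.array([r.n for r in records], dtype=float)
    if method == "unweighted":
        return float(d.mean())
    if method != "fixed_inverse_variance":
        raise ValueError(f"unknown method: {method!r}")
    var = 1.0 / n + d**2 / (2.0 * n)
    w = 1.0 / var
    return float(np.sum(w * d) / np.sum(w))


def sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    method: str = "normal_approx",
) -> int:
    """Participants needed to detect a within-participant effect d.

    ``normal_approx`` is the standard z-based formula; ``noncentral_t``
    searches for the smallest n whose exact one-sample t power reaches the
    target (always >= the approximation, which ignores the estimated SD).
    Minimum 2 in all cases.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = sps.norm.ppf(1 - alpha / tails)
    z_b = sps.norm.ppf(power)
    n_norm = max(2, int(np.ceil(((z_a + z_b) / d) ** 2)))
    if method == "normal_approx":
        return n_norm
    if method != "noncentral_t":
        raise ValueError(f"unknown method: {method!r}")

    def achieved_power(n: int) -> float:
        df = n - 1
        tcrit = sps.t.ppf(1 - alpha / tails, df)
        nc = d * np.sqrt(n)
        pw = sps.nct.sf(tcrit, df, nc)
        if tails == 2:
            pw += sps.nct.cdf(-tcrit, df, nc)
        return float(pw)

    n = n_norm
    while achieved_power(n) < power:
        n += 1
    return max(2, n)


def rmt_effect_correlation(rmt, effect) -> tuple[float, int, float]:
    """Pearson correlation of resting motor threshold with effect size.

    Returns (r, df = n - 2, two-tailed p).  Zero variance in either
    variable is a signalled error.
    """
    x = np.asarray(rmt, dtype=float)
    y = np.asarray(effect, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), x.size - 2, float(p)


def proportion_pct(count: int, total: int, ndigits: int = 1) -> float:
    """A count as a percentage of a total (e.g. rater detection rates)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return round(100.0 * count / total, ndigits)
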
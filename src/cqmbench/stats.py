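"""Rate uncertainty: percentile-bootstrap confidence intervals.

The statistic is a compliance proportion over the measure's denominator
units (patients, or encounters for the COPD measure).  Each bootstrap
resample draws ``n`` units with replacement from the observed boolean
compliance vector; for a binary vector the resampled numerator count is
therefore exactly Binomial(n, k/n), which is how the resampling is
computed (identical distribution, no O(n) vector shuffling).
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass(frozen=True)
class BootstrapSettings:
    """Resample count, significance level and RNG seed (all mandatory inputs).

    Defaults follow the usual convention of 1000 resamples for a 95%
    percentile interval.
    """

    resamples: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.resamples < 1:
            raise ValueError("resamples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def bootstrap_ci(unit_flags, settings: BootstrapSettings) -> tuple[float, float] | None:
    """Percentile bootstrap interval for the compliance proportion.

    ``unit_flags`` is the per-unit boolean compliance vector of the
    denominator units.  Returns ``(ci_low, ci_high)``, or ``None`` for an
    empty vector (the undefined-CI signal).  Deterministic given the seed.
    """
    flags = np.asarray(unit_flags, dtype=bool)
    n = flags.size
    if n == 0:
        return None
    k = int(flags.sum())
    p_hat = k / n
    if k == 0 or k == n:  # resampling a constant vector is degenerate
        return (float(p_hat), float(p_hat))
    rng = np.random.default_rng(settings.seed)
    draws = rng.binomial(n, p_hat, size=settings.resamples) / n
    lo, hi = np.quantile(draws, [settings.alpha / 2, 1 - settings.alpha / 2])
    return (float(lo), float(hi))
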
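"""Normal vs log-normal diagnostics via probability-plot correlation.

Many RT-DC readouts (deformation in particular) are bounded below and in
the small-deformation regime pile up against that bound, so they tend to
be log-normally rather than normally distributed.  The diagnostic here is
the classic probability-plot correlation: sort the sample, place it
against the standard-normal inverse CDF of Filliben's order-statistic
probabilities, and measure the squared linear correlation R².  Repeating
after a natural-log transform gives R²′; the larger of the two names the
better-fitting family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ProbPlotResult",
    "filliben_quantiles",
    "probability_plot_r2",
    "compare_normal_lognormal",
]


@dataclass(frozen=True)
class ProbPlotResult:
    """Outcome of the normal vs log-normal comparison for one feature."""

    r2: float
    r2_log: float
    n: int
    verdict: str  # "normal" | "lognormal" | "tie"
    log_branch_skipped: bool = False


def filliben_quantiles(n: int) -> np.ndarray:
    """Filliben's order-statistic probability estimates m_1..m_n.

    m_1 = 1 − 0.5^(1/n), m_i = (i − 0.3175)/(n + 0.365) for the interior,
    m_n = 0.5^(1/n); strictly increasing, all in (0, 1), and symmetric
    about ½ in the interior (m_i + m_{n+1−i} = 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([0.5])
    m = (np.arange(1, n + 1) - 0.3175) / (n + 0.365)
    m[-1] = 0.5 ** (1.0 / n)
    m[0] = 1.0 - m[-1]
    return m


def probability_plot_r2(values: np.ndarray) -> float:
    """Squared correlation of the normal probability plot of ``values``.

    The ordered sample is correlated against Φ⁻¹(m_i) at Filliben's
    probabilities; values near 1 indicate Gaussian behavior.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if v[0] == v[-1]:
        raise ValueError("constant sample has no probability plot")
    theo = stats.norm.ppf(filliben_quantiles(n))
    r = np.corrcoef(theo, v)[0, 1]
    return float(r * r)


def compare_normal_lognormal(values: np.ndarray) -> ProbPlotResult:
    """R² for the raw and the log-transformed sample, with a verdict.

    Verdict is ``lognormal`` iff R²(log data) > R²(raw data).  The log
    branch requires strictly positive values; otherwise it is skipped
    and flagged, and the verdict defaults to ``normal``.
    """
    v = np.asarray(values, dtype=float)
    r2 = probability_plot_r2(v)
    if np.any(v <= 0):
        return ProbPlotResult(r2=r2, r2_log=np.nan, n=v.size,
                              verdict="normal", log_branch_skipped=True)
    r2_log = probability_plot_r2(np.log(v))
    if r2_log > r2:
        verdict = "lognormal"
    elif r2_log < r2:
        verdict = "normal"
    else:
        verdict = "tie"
    return ProbPlotResult(r2=r2, r2_log=r2_log, n=v.size, verdict=verdict)
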
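"""Group-level inference on decoding accuracies.

Accuracy is compared against chance with planned one-tailed one-sample
t-tests (the hypothesis is always "greater than chance") and between
conditions with planned two-tailed paired t-tests; effect sizes are
Cohen's d (for paired comparisons, the mean difference divided by the SD
of the differences). No multiple-testing correction is applied by default;
Holm correction is available for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupStats", "StatsError", "one_sample_t", "paired_t", "holm_correct"]


class StatsError(ValueError):
    """Degenerate statistical input."""


@dataclass(frozen=True)
class GroupStats:
    """t-statistic, p-value and Cohen's d of one planned comparison."""

    t: float
    p: float
    d: float
    n: int
    tail: str
    comparison: str = ""

    @property
    def df(self) -> int:
        return self.n - 1


def _check(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise StatsError(f"{what} needs at least 2 values")
    if values.std(ddof=1) == 0:
        raise StatsError(f"{what} has zero variance")
    return values


def one_sample_t(
    values: Sequence[float], null_value: float, tail: str = "one", comparison: str = ""
) -> GroupStats:
    """One-sample t-test of ``values`` against ``null_value``.

    ``tail="one"`` tests the upper tail (greater than the null, the planned
    direction for accuracy-vs-chance tests); ``tail="two"`` is two-sided.
    Cohen's d is ``(mean - null)/sd``.
    """
    v = _check(values, "one-sample t input")
    n = v.size
    sd = v.std(ddof=1)
    t = (v.mean() - null_value) / (sd / np.sqrt(n))
    if tail == "one":
        p = float(_sps.t.sf(t, df=n - 1))
    elif tail == "two":
        p = float(2 * _sps.t.sf(abs(t), df=n - 1))
    else:
        raise StatsError(f"tail must be 'one' or 'two', got {tail!r}")
    d = (v.mean() - null_value) / sd
    return GroupStats(float(t), p, float(d), n, tail, comparison)


def paired_t(
    a: Sequence[float], b: Sequence[float], tail: str = "two", comparison: str = ""
) -> GroupStats:
    """Paired t-test of ``a`` vs ``b``: a one-sample t on the differences.

    Cohen's d uses the standard deviation of the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    return one_sample_t(a - b, 0.0, tail=tail, comparison=comparison)


def holm_correct(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (exploratory use only)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
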
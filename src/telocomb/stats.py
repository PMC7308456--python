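"""Length-distribution statistics.

Summaries use Tukey's boxplot conventions (quartiles by linear interpolation
of order statistics, whiskers at the most extreme observations within 1.5
IQR of the quartiles). Group comparisons are the two-sided Student t-test
for data treated as normal and the two-sided Mann-Whitney U test otherwise;
the caller chooses, normality is never auto-tested. Method agreement is
ordinary least squares with its R^2. The telomere attrition rate is the
negated OLS slope of mean length (kb) against population doubling,
expressed in bp per doubling. The flow-FISH relative telomere length is
the standard ratio of background-subtracted mean fluorescence intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, MeasurementError
from .measure import LengthDistribution

EXACT_MANN_WHITNEY_MAX_N = 20


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sem: float
    median: float
    min: float
    max: float
    q1: float
    q3: float
    tukey_whisker_low: float
    tukey_whisker_high: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class FlowFishRecord:
    """Mean fluorescence intensities of a flow-FISH run: experimental and
    control (CCRF-CEM) populations, each with and without the PNA probe."""

    fi_exp_probe: float
    fi_exp_noprobe: float
    fi_ctrl_probe: float
    fi_ctrl_noprobe: float

    def __post_init__(self) -> None:
        if not self.fi_ctrl_probe > self.fi_ctrl_noprobe:
            raise ConfigurationError(
                "control probe signal must exceed control background "
                f"({self.fi_ctrl_probe} <= {self.fi_ctrl_noprobe})"
            )


def _as_lengths(dist) -> np.ndarray:
    if isinstance(dist, LengthDistribution):
        return dist.lengths
    return np.asarray(dist, dtype=float)


def summarize(dist) -> SummaryStats:
    """Distribution summary: n, mean +/- SEM, median, extremes, quartiles
    and Tukey whiskers. Order-invariant; requires n >= 1."""
    x = _as_lengths(dist)
    if x.size < 1:
        raise MeasurementError("cannot summarize an empty distribution")
    n = int(x.size)
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear (type-7) interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return SummaryStats(
        n=n,
        mean=float(np.mean(x)),
        sem=sem,
        median=float(med),
        min=float(np.min(x)),
        max=float(np.max(x)),
        q1=float(q1),
        q3=float(q3),
        tukey_whisker_low=float(inside.min()),
        tukey_whisker_high=float(inside.max()),
    )


def compare(a, b, test: str = "t") -> tuple[float, float]:
    """Two-sided comparison of two samples.

    ``test='t'`` is Student's t-test (pooled variance); ``'mann_whitney'``
    uses the exact null distribution of U when the combined sample size is
    at most 20 and there are no ties, and the tie-corrected normal
    approximation otherwise. Returns (statistic, p_value).
    """
    x = _as_lengths(a)
    y = _as_lengths(b)
    if x.size < 2 or y.size < 2:
        raise MeasurementError("each sample needs n >= 2")
    if test == "t":
        res = sps.ttest_ind(x, y, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        combined = np.concatenate([x, y])
        has_ties = np.unique(combined).size < combined.size
        if combined.size <= EXACT_MANN_WHITNEY_MAX_N and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ConfigurationError(f"unknown test {test!r}; use 't' or 'mann_whitney'")


def regress(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns
    (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise MeasurementError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise MeasurementError("x is constant: regression is degenerate")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def attrition_rate(points) -> float:
    """Telomere attrition in bp per population doubling.

    ``points`` is a sequence of (population_doubling, mean_length_kb); the
    rate is -1000 times the OLS slope of kb against PD, so shortening is
    positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ConfigurationError("need >= 2 (PD, mean_kb) points")
    pd_, kb = pts[:, 0], pts[:, 1]
    if np.ptp(pd_) == 0:
        raise MeasurementError("population doublings are all identical")
    xc = pd_ - pd_.mean()
    slope = float(xc @ (kb - kb.mean()) / (xc @ xc))
    return -1000.0 * slope


def flow_fish_rtl(rec: FlowFishRecord) -> float:
    """Relative telomere length from flow-FISH mean fluorescence
    intensities: background-subtracted experimental signal over
    background-subtracted control signal. Equals 1 when the experimental
    population matches the control."""
    denom = rec.fi_ctrl_probe - rec.fi_ctrl_noprobe
    return (rec.fi_exp_probe - rec.fi_exp_noprobe) / denom
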
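"""Cohort percentile banding.

Reference percentile curves (1st, 10th, 50th, 90th, 99th telomere length
percentiles as a function of age, e.g. from a cohort of healthy controls)
are consumed as data; an individual's (age, length) is assigned to the band
its value falls in after linear interpolation of the curves at that age.
Telomere biology disorders typically place individuals below the 1st-10th
percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PERCENTILE_COLUMNS = ["p1", "p10", "p50", "p90", "p99"]
BANDS = ["<1st", "1st-10th", "10th-50th", "50th-90th", "90th-99th", ">99th"]


@dataclass(frozen=True)
class CohortReference:
    """Age-resolved percentile curves in consistent length units.

    ``ages`` strictly increasing; each row of ``percentiles`` holds
    (p1, p10, p50, p90, p99), non-decreasing across the row.
    """

    ages: np.ndarray
    percentiles: np.ndarray  # shape (n_ages, 5)
    units: str = "kb"
    clamp_age: bool = False

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        pct = np.asarray(self.percentiles, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "percentiles", pct)
        if ages.ndim != 1 or pct.shape != (ages.size, 5):
            raise ConfigurationError("need ages (n,) and percentiles (n, 5)")
        if ages.size < 1:
            raise ConfigurationError("reference needs at least one age row")
        if ages.size > 1 and not (np.diff(ages) > 0).all():
            raise ConfigurationError("ages must be strictly increasing")
        if not (np.diff(pct, axis=1) >= 0).all():
            raise ConfigurationError("percentiles must be non-decreasing within each row")

    def interpolate(self, age: float) -> np.ndarray:
        """Percentile values (p1..p99) at an age, linearly interpolated."""
        if not self.clamp_age and not (self.ages[0] <= age <= self.ages[-1]):
            raise ConfigurationError(
                f"age {age} outside reference range "
                f"[{self.ages[0]}, {self.ages[-1]}] (enable clamp_age to extrapolate)"
            )
        return np.array(
            [np.interp(age, self.ages, self.percentiles[:, k]) for k in range(5)]
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "CohortReference":
        df = pd.read_csv(Path(path))
        missing = [c for c in ["age"] + PERCENTILE_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"cohort reference CSV missing columns: {missing}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df[PERCENTILE_COLUMNS].to_numpy(), **kw)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.percentiles, columns=PERCENTILE_COLUMNS)
        df.insert(0, "age", self.ages)
        df.to_csv(path, index=False)
        return path


def percentile_band(age: float, value: float, ref: CohortReference) -> str:
    """Band of the reference distribution containing ``value`` at ``age``.

    Boundary values belong to the lower band (a value exactly on the
    interpolated median is "10th-50th"); monotone non-decreasing in value
    at fixed age.
    """
    p1, p10, p50, p90, p99 = ref.interpolate(age)
    if value <= p1:
        return "<1st"
    if value <= p10:
        return "1st-10th"
    if value <= p50:
        return "10th-50th"
    if value <= p90:
        return "50th-90th"
    if value <= p99:
        return "90th-99th"
    return ">99th"
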
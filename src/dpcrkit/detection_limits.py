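"""Limit-of-blank / limit-of-detection statistics for a mutation class.

A dilution series of a mutant sequence (e.g. a synthetic large-deletion
cassette) in a wildtype background calibrates how small a mutant fraction
the assay can distinguish from blank-level noise:

    LoB = mean(blanks) + 1.645 * sd(blanks)
    LoD = LoB + 1.645 * sd(lowest dilution level whose mean exceeds LoB)

1.645 is the one-sided 95% normal quantile; the sample (n-1) standard
deviation is used throughout. Measurements are reference-normalised and
dilution-factor corrected before comparison; both raw and corrected values
are stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DetectionFailure, InputError

__all__ = ["DilutionSeries", "LoDReport", "limit_of_blank", "limit_of_detection"]

ONE_SIDED_95 = 1.645


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution of true mutant fractions with replicate observations.

    ``observed`` is a list (one entry per level, sorted by descending
    expected fraction) of replicate arrays of dilution-corrected,
    reference-normalised measurements; ``raw_observed`` optionally keeps the
    uncorrected values.
    """

    expected_fraction: tuple[float, ...]
    observed: tuple[tuple[float, ...], ...]
    raw_observed: tuple[tuple[float, ...], ...] | None = None
    dilution_factors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.expected_fraction) != len(self.observed):
            raise InputError("expected and observed lists differ in length")
        if any(not 0 <= f <= 1 for f in self.expected_fraction):
            raise InputError("expected fractions must lie in [0, 1]")
        if list(self.expected_fraction) != sorted(
            self.expected_fraction, reverse=True
        ):
            raise InputError("dilution levels must be sorted descending")

    @classmethod
    def from_arrays(cls, expected, observed, raw_observed=None, dilution_factors=None):
        order = np.argsort(expected)[::-1]
        expected = tuple(float(expected[i]) for i in order)
        observed = tuple(tuple(float(v) for v in observed[i]) for i in order)
        if raw_observed is not None:
            raw_observed = tuple(
                tuple(float(v) for v in raw_observed[i]) for i in order
            )
        if dilution_factors is not None:
            dilution_factors = tuple(float(dilution_factors[i]) for i in order)
        return cls(expected, observed, raw_observed, dilution_factors)

    def level_mean(self, i: int) -> float:
        return float(np.mean(self.observed[i]))

    def level_sd(self, i: int) -> float:
        arr = np.asarray(self.observed[i], dtype=float)
        return float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass(frozen=True)
class LoDReport:
    lob: float
    lod: float
    lowest_level_expected: float
    slope: float
    intercept: float
    r2: float
    sd_low: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lob": self.lob,
            "lod": self.lod,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
        }


def limit_of_blank(blank_values) -> float:
    """One-sided 95% upper bound on blank measurements.

    LoB = mean + 1.645 * sd (sample sd, n-1 denominator). At least two
    blank measurements are required.
    """
    arr = np.asarray(list(blank_values), dtype=float)
    if arr.size < 2:
        raise InputError("limit_of_blank needs at least 2 blank measurements")
    return float(arr.mean() + ONE_SIDED_95 * arr.std(ddof=1))


def limit_of_detection(lob: float, series: DilutionSeries) -> LoDReport:
    """LoD from the lowest dilution level detectable above the LoB.

    LoD = LoB + 1.645 * sd(lowest level whose mean exceeds LoB). Also fits
    an ordinary least-squares regression of observed on expected fraction
    over the whole series (slope, intercept, R^2) as a linearity check.

    Raises
    ------
    DetectionFailure
        If no dilution level's mean exceeds the LoB.
    """
    above = [i for i in range(len(series.expected_fraction))
             if series.level_mean(i) > lob]
    if not above:
        raise DetectionFailure("no dilution level detected above the limit of blank")
    # levels are sorted descending, so the last qualifying index is lowest
    low = max(above)
    sd_low = series.level_sd(low)
    lod = lob + ONE_SIDED_95 * sd_low

    x = np.repeat(series.expected_fraction,
                  [len(o) for o in series.observed]).astype(float)
    y = np.concatenate([np.asarray(o, dtype=float) for o in series.observed])
    if np.unique(x).size >= 2:
        res = stats.linregress(x, y)
        slope, intercept, r2 = (
            float(res.slope), float(res.intercept), float(res.rvalue**2)
        )
    else:  # a single dilution level cannot constrain linearity
        slope = intercept = r2 = float("nan")
    return LoDReport(
        lob=lob,
        lod=lod,
        lowest_level_expected=series.expected_fraction[low],
        slope=slope,
        intercept=intercept,
        r2=r2,
        sd_low=sd_low,
    )
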
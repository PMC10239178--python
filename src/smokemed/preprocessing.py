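"""Variable preparation: extreme-outlier fences, outcome transforms, skewness.

Extreme outliers follow the 3x-IQR Tukey fence: values outside
[Q1 - 3*(Q3-Q1), Q3 + 3*(Q3-Q1)] are excluded, with quartiles estimated by
linear interpolation between order statistics (configurable).  Outcomes are
optionally natural-log transformed (the right-skewed glycaemic outcomes)
and always standardised as z-scores with the sample SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DomainError


@dataclass(frozen=True)
class OutlierRule:
    """Tukey fence with multiplier 3 for a single variable."""

    q1: float
    q3: float
    multiplier: float = 3.0

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower_bound(self) -> float:
        return self.q1 - self.multiplier * self.iqr

    @property
    def upper_bound(self) -> float:
        return self.q3 + self.multiplier * self.iqr

    @classmethod
    def from_values(cls, values, multiplier: float = 3.0,
                    method: str = "linear") -> "OutlierRule":
        """Estimate the fence from the non-missing values of a series."""
        vals = np.asarray(pd.Series(values).dropna(), dtype=float)
        if vals.size == 0:
            raise DegenerateInputError("cannot compute quartiles of an all-missing series")
        q1, q3 = np.quantile(vals, [0.25, 0.75], method=method)
        return cls(q1=float(q1), q3=float(q3), multiplier=multiplier)

    def mask(self, values) -> pd.Series:
        """Boolean keep-mask: True for in-bounds or missing values."""
        s = pd.Series(values, dtype=float)
        out = (s < self.lower_bound) | (s > self.upper_bound)
        return ~out.fillna(False)


def flag_extreme_outliers(values, multiplier: float = 3.0,
                          method: str = "linear") -> pd.Series:
    """Keep-mask for the 3x-IQR extreme-outlier rule.

    Returns a boolean series aligned with the input: False exactly for the
    non-missing values outside the fence; missing values are never flagged
    (they stay True and pass through as missing downstream).

    Requires at least 4 non-missing values so the quartiles are meaningful.
    """
    s = pd.Series(values, dtype=float)
    n_obs = int(s.notna().sum())
    if n_obs == 0:
        raise DegenerateInputError("all values missing")
    if n_obs < 4:
        raise DegenerateInputError(f"need >= 4 non-missing values, got {n_obs}")
    return OutlierRule.from_values(s, multiplier=multiplier, method=method).mask(s)


@dataclass(frozen=True)
class TransformSpec:
    """Outcome transform: optional natural log, then z-score standardisation."""

    log_transform: bool = False
    standardize: bool = True


def transform_outcome(values, spec: TransformSpec) -> pd.Series:
    """Apply the transform; the reference sample is the series' non-missing part.

    The returned series has mean 0 and (sample, n-1) SD 1 over the reference
    sample when ``standardize`` is set; missing values are preserved.
    """
    s = pd.Series(values, dtype=float)
    if spec.log_transform:
        bad = s.index[(s <= 0).fillna(False)]
        if len(bad):
            raise DomainError(
                f"log transform requires strictly positive values; "
                f"offending rows: {list(bad[:5])}")
        s = np.log(s)
    if spec.standardize:
        obs = s.dropna()
        if len(obs) < 2:
            raise DegenerateInputError("need >= 2 non-missing values to standardize")
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError("zero variance: cannot standardize")
        s = (s - obs.mean()) / sd
    return s


def sample_skewness(values) -> float:
    """Fisher-Pearson standardised third moment g1 = m3 / m2^(3/2).

    Biased (population-moment) convention, i.e. no small-sample adjustment.
    """
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if vals.size < 3:
        raise DegenerateInputError(f"need >= 3 non-missing values, got {vals.size}")
    if np.var(vals) == 0:
        raise DegenerateInputError("zero variance: skewness undefined")
    return float(stats.skew(vals, bias=True))
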
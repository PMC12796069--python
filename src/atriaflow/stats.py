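"""Test-retest repeatability statistics.

For paired measurements (test, retest) per subject:

* RPC, repeatability coefficient: 2 x SD of the paired differences
  (sample SD, n-1 denominator).
* CoV, coefficient of variation (%): SD of differences / grand mean x 100.
* ICC, two-way mixed, single-score intraclass correlation.  "Consistency"
  (ICC(3,1)) is the default reading; the absolute-agreement form (ICC(2,1))
  is reported alongside because the convention is often left unstated.
* Bland-Altman mean difference and 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

__all__ = ["PairedMeasurements", "RepeatabilityStats", "repeatability_stats"]


@dataclass
class PairedMeasurements:
    """A (subject, test, retest) table in consistent units."""

    subject: np.ndarray
    test: np.ndarray
    retest: np.ndarray

    def __post_init__(self):
        self.test = np.asarray(self.test, float)
        self.retest = np.asarray(self.retest, float)
        self.subject = np.asarray(self.subject)
        if self.test.shape != self.retest.shape or self.test.ndim != 1:
            raise InputError("test and retest must be 1-D arrays of equal length")
        if self.test.size < 2:
            raise InputError("need at least 2 paired measurements")
        if not (np.isfinite(self.test).all() and np.isfinite(self.retest).all()):
            raise InputError("paired measurements must be finite")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairedMeasurements":
        return cls(frame["subject"].to_numpy(), frame["test"].to_numpy(), frame["retest"].to_numpy())


@dataclass
class RepeatabilityStats:
    rpc: float
    cov_pct: float
    icc: float            # two-way mixed, single score, consistency ICC(3,1)
    icc_absolute: float   # absolute agreement ICC(2,1)
    mean_diff: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("rpc", "cov_pct", "icc", "icc_absolute", "mean_diff", "loa_low", "loa_high", "n")}


def _icc_anova(values: np.ndarray) -> tuple[float, float]:
    """(consistency ICC(3,1), absolute ICC(2,1)) from an (n, k) table."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    denom_c = ms_rows + (k - 1) * ms_err
    icc_c = (ms_rows - ms_err) / denom_c if denom_c > 0 else np.nan
    denom_a = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    icc_a = (ms_rows - ms_err) / denom_a if denom_a > 0 else np.nan
    return float(icc_c), float(icc_a)


def repeatability_stats(pairs: PairedMeasurements) -> RepeatabilityStats:
    """RPC, CoV, ICC and Bland-Altman limits for a paired table."""
    d = pairs.test - pairs.retest
    sd = float(np.std(d, ddof=1))
    rpc = 2.0 * sd
    grand = float(np.concatenate([pairs.test, pairs.retest]).mean())
    if grand == 0:
        raise ParameterError("grand mean is zero: CoV undefined")
    cov = sd / grand * 100.0
    icc_c, icc_a = _icc_anova(np.stack([pairs.test, pairs.retest], axis=1))
    mean_diff = float(d.mean())
    return RepeatabilityStats(
        rpc=rpc,
        cov_pct=cov,
        icc=icc_c,
        icc_absolute=icc_a,
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        n=int(d.size),
    )
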
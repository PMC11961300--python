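"""Measurement reliability: agreement ICC and Dahlberg's random error.

Systematic error between two measurement occasions (or examiners) is
quantified with the two-way, absolute-agreement, single-measure
intraclass correlation ICC(A,1) of McGraw & Wong; random error with
Dahlberg's statistic sqrt(sum(d_i^2) / 2n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReplicatePairs", "icc_agreement", "dahlberg", "reliability_table"]


class UndefinedCoefficientError(ZeroDivisionError):
    """The agreement coefficient is undefined (no variance in the data)."""


@dataclass(frozen=True)
class ReplicatePairs:
    """Paired duplicate measurements of one trait (mm)."""

    trait: str
    values1: np.ndarray
    values2: np.ndarray

    def __post_init__(self) -> None:
        v1 = np.asarray(self.values1, dtype=float)
        v2 = np.asarray(self.values2, dtype=float)
        if v1.shape != v2.shape or v1.ndim != 1:
            raise ValueError("values1 and values2 must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
            raise ValueError("replicate values must be finite")
        object.__setattr__(self, "values1", v1)
        object.__setattr__(self, "values2", v2)

    @property
    def n(self) -> int:
        return self.values1.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait: str = "") -> "ReplicatePairs":
        return cls(trait or str(df.get("trait", pd.Series(["" ])).iloc[0]),
                   df["value1"].to_numpy(), df["value2"].to_numpy())


def icc_agreement(rp: ReplicatePairs) -> float:
    """Two-way absolute-agreement single-measure ICC(A,1).

    From the two-way ANOVA mean squares with k = 2 raters/occasions:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC, MSE are the rows (subjects), columns (occasions) and
    error mean squares. A constant column offset between occasions lowers
    the coefficient: absolute agreement penalises systematic bias.
    Negative estimates are returned as computed, not truncated.
    """
    n, k = rp.n, 2
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    y = np.column_stack([rp.values1, rp.values2])
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300 or ss_total == 0.0:
        raise UndefinedCoefficientError(
            f"{rp.trait or 'trait'}: zero total variance, ICC undefined"
        )
    return float((msr - mse) / denom)


def dahlberg(rp: ReplicatePairs) -> float:
    """Dahlberg's random-error estimate sqrt(sum(d^2) / 2n), in mm.

    For independent measurement errors of SD sigma, E(d^2) = 2 sigma^2, so
    the statistic converges to sigma.
    """
    d = rp.values1 - rp.values2
    return float(np.sqrt(np.sum(d * d) / (2.0 * rp.n)))


def reliability_table(replicates: dict[str, ReplicatePairs]) -> pd.DataFrame:
    """Per-trait ICC(A,1) and Dahlberg error table."""
    rows = []
    for trait, rp in replicates.items():
        try:
            icc = icc_agreement(rp)
            note = "negative ICC" if icc < 0 else ""
        except UndefinedCoefficientError:
            icc, note = np.nan, "zero variance"
        rows.append({"trait": trait, "n": rp.n, "icc_a1": icc,
                     "dahlberg_mm": dahlberg(rp), "note": note})
    return pd.DataFrame(rows)
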
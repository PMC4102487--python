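"""Agreement statistics for paired length/volume measurements.

Validation compares two measurement sources (automated vs. reference, or
two human raters) per case with the intraclass correlation coefficient
and a Bland-Altman analysis (bias and 1.96-SD limits of agreement).  The
default ICC is the two-way random-effects, absolute-agreement,
single-measure coefficient — ICC(2,1) — so a constant offset between the
methods counts as disagreement; the consistency variant ICC(3,1) is
available as a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementPairs",
    "AgreementReport",
    "icc",
    "bland_altman",
    "cohort_report",
    "CohortReport",
]


@dataclass
class MeasurementPairs:
    """Paired per-case measurements by two methods/raters."""

    labels: list
    a: np.ndarray
    b: np.ndarray
    quantity: str = "length"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.labels) == len(self.a) == len(self.b)):
            raise ValueError("labels, a and b must have equal length")
        if len(self.a) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass
class AgreementReport:
    """ICC plus Bland-Altman bias and limits of agreement."""

    icc: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    quantity: str = ""
    flags: list[str] = field(default_factory=list)


def icc(pairs: MeasurementPairs, variant: str = "ICC(2,1)") -> float:
    """Single-measure intraclass correlation from the two-way ANOVA mean
    squares of the n-case x 2-rater table.

    ``variant``: "ICC(2,1)" (absolute agreement, default) or "ICC(3,1)"
    (consistency).  Degenerate zero-variance inputs: identical constant
    raters give 1.0 (perfect agreement, with a warning); any other
    zero-variance table is undefined and returns NaN with a warning.
    """
    x = np.column_stack([pairs.a, pairs.b])
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        warnings.warn("zero total variance: constant identical raters, ICC := 1")
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "ICC(2,1)":
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
    elif variant == "ICC(3,1)":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        warnings.warn("zero between-target variance: ICC undefined")
        return float("nan")
    return float((msr - mse) / denom)


def bland_altman(pairs: MeasurementPairs, icc_variant: str = "ICC(2,1)") -> AgreementReport:
    """Bias = mean(a - b); limits = bias ± 1.96 × sample SD (n−1) of the
    paired differences.  The matching ICC is included for convenience."""
    d = pairs.a - pairs.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        icc=icc(pairs, icc_variant),
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=pairs.n,
        quantity=pairs.quantity,
    )


@dataclass
class CohortReport:
    """Per-quantity agreement plus per-case residual table."""

    table: pd.DataFrame
    reports: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            q: {
                "icc": r.icc,
                "bias": r.bias,
                "sd_diff": r.sd_diff,
                "loa_lower": r.loa_lower,
                "loa_upper": r.loa_upper,
                "n": r.n,
            }
            for q, r in self.reports.items()
        }


def cohort_report(results: dict, truth: dict) -> CohortReport:
    """Agreement of automated measurements against per-case ground truth.

    ``results`` maps case id -> (length_mm, volume_mm3) or an object with
    ``length_mm``/``volume_mm3`` attributes; ``truth`` likewise (e.g. a
    phantom's ground truth).  Unmatched ids are rejected by name.
    """
    missing = sorted(set(results) ^ set(truth))
    if missing:
        raise ValueError(f"unmatched case ids: {missing}")

    def unpack(v):
        if hasattr(v, "length_mm"):
            return float(v.length_mm), float(getattr(v, "volume_mm3", np.nan))
        if hasattr(v, "true_length_mm"):
            return float(v.true_length_mm), float(v.true_volume_mm3)
        return float(v[0]), float(v[1])

    rows = []
    for cid in sorted(results):
        al, av = unpack(results[cid])
        tl, tv = unpack(truth[cid])
        rows.append(
            dict(case_id=cid, length_auto=al, length_true=tl,
                 volume_auto=av, volume_true=tv,
                 length_residual=al - tl, volume_residual=av - tv,
                 length_mean=(al + tl) / 2, volume_mean=(av + tv) / 2)
        )
    table = pd.DataFrame(rows)
    reports = {}
    for q in ("length", "volume"):
        pairs = MeasurementPairs(
            labels=list(table["case_id"]),
            a=table[f"{q}_auto"].to_numpy(),
            b=table[f"{q}_true"].to_numpy(),
            quantity=q,
        )
        reports[q] = bland_altman(pairs)
    return CohortReport(table=table, reports=reports)
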
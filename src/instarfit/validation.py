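"""Instar-count validation: summary statistics, growth-ratio indices,
homogeneity criteria, and Dyar's-rule regression.

Once measurements are partitioned into putative instars, three classical
checks confirm that the partition neither merged nor split an instar:

* the within-instar coefficient of variation (CV) should be small
  (default criterion: below 15%) — a large CV suggests two instars were
  merged;
* Brooks' index, the growth ratio ``x_n / x_{n−1}`` of successive mean
  widths, should be roughly constant, which Crosby's index quantifies as
  the relative change between successive Brooks indices (default
  criterion: magnitude below 0.1);
* Dyar's rule: mean width grows by a near-constant factor per instar, so
  ``ln(mean HCW)`` is close to linear in instar number and the regression
  R² should be near 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import HCWDataset
from .mixture import InstarPartition


@dataclass(frozen=True)
class InstarStats:
    """Summary statistics for one instar's head-capsule widths (μm)."""

    instar: int
    count: int
    mean: float
    sd: float
    se: float
    cv: float  # percent, 100·sd/mean


@dataclass(frozen=True)
class InstarValidationReport:
    """Per-instar statistics plus Brooks'/Crosby's indices and verdicts.

    ``brooks`` has one entry per instar from the second onward (k−1
    entries); ``crosby`` one per instar from the third onward (k−2).
    """

    per_instar: tuple[InstarStats, ...]
    brooks: tuple[float, ...]
    crosby: tuple[float, ...]
    cv_pass: tuple[bool, ...]
    crosby_pass: tuple[bool, ...]
    cv_threshold: float
    crosby_threshold: float

    @property
    def k(self) -> int:
        return len(self.per_instar)

    @property
    def overall_pass(self) -> bool:
        return all(self.cv_pass) and all(self.crosby_pass)

    def to_frame(self) -> pd.DataFrame:
        """Validation table: instar, n, mean, SE, CV, Brooks, Crosby."""
        rows = []
        for i, s in enumerate(self.per_instar):
            rows.append(
                {
                    "instar": s.instar,
                    "n": s.count,
                    "mean_um": s.mean,
                    "se_um": s.se,
                    "cv_percent": s.cv,
                    "brooks": self.brooks[i - 1] if i >= 1 else math.nan,
                    "crosby": self.crosby[i - 2] if i >= 2 else math.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().round(4).to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        doc = {
            "per_instar": [asdict(s) for s in self.per_instar],
            "brooks": list(self.brooks),
            "crosby": list(self.crosby),
            "cv_pass": list(self.cv_pass),
            "crosby_pass": list(self.crosby_pass),
            "cv_threshold": self.cv_threshold,
            "crosby_threshold": self.crosby_threshold,
            "overall_pass": self.overall_pass,
        }
        return json.dumps(doc, indent=2, sort_keys=True)


@dataclass(frozen=True)
class CriteriaVerdict:
    """Outcome of the homogeneity/separation criteria for a report."""

    cv_pass: tuple[bool, ...]
    crosby_pass: tuple[bool, ...]
    overall: bool


@dataclass(frozen=True)
class DyarRegressionResult:
    """OLS fit of ln(mean HCW) on instar number.

    ``slope`` is the per-instar increment of ln(mean HCW), so
    ``exp(slope)`` estimates the common Dyar growth factor. ``f_stat``
    carries df (1, k−2); with only k=3 instars the p-value is nearly
    uninformative and is reported, never gated on.
    """

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n_points: int


def instar_stats(
    data: HCWDataset | np.ndarray, partition: InstarPartition
) -> tuple[InstarStats, ...]:
    """Per-instar count, mean, SD, SE, and CV, in ascending instar order.

    SD uses the n−1 (sample) denominator, conventional for small
    morphometric samples; a single-member instar gets SD 0. An instar
    with zero members is an error — the partition does not describe the
    data it was applied to.
    """
    values = data.values if isinstance(data, HCWDataset) else np.asarray(data, float)
    labels = partition.assignments
    if labels.size != values.size:
        raise ValueError("partition does not cover the dataset")
    out = []
    for instar in range(1, partition.k + 1):
        members = values[labels == instar]
        if members.size == 0:
            raise ValueError(f"instar {instar} has no members")
        mean = float(members.mean())
        sd = float(members.std(ddof=1)) if members.size > 1 else 0.0
        out.append(
            InstarStats(
                instar=instar,
                count=int(members.size),
                mean=mean,
                sd=sd,
                se=sd / math.sqrt(members.size),
                cv=100.0 * sd / mean,
            )
        )
    return tuple(out)


def brooks_index(mean_n: float, mean_prev: float) -> float:
    """Growth ratio between successive instars: ``x_n / x_{n−1}``."""
    if mean_n <= 0 or mean_prev <= 0:
        raise ValueError("means must be > 0")
    return mean_n / mean_prev


def crosby_index(b_n: float, b_prev: float) -> float:
    """Relative change between successive Brooks indices:
    ``(b_n − b_{n−1}) / b_{n−1}``."""
    if b_prev == 0:
        raise ValueError("previous Brooks index must be nonzero")
    return (b_n - b_prev) / b_prev


def validation_report(
    stats: Sequence[InstarStats],
    cv_threshold: float = 15.0,
    crosby_threshold: float = 0.1,
) -> InstarValidationReport:
    """Assemble the full validation report from per-instar statistics.

    The Crosby criterion is applied to the index magnitude: a negative
    Crosby index of small absolute value indicates a slightly decreasing
    growth ratio and is equally consistent with no missed instar.
    """
    means = [s.mean for s in stats]
    brooks = tuple(brooks_index(means[i], means[i - 1]) for i in range(1, len(means)))
    crosby = tuple(crosby_index(brooks[i], brooks[i - 1]) for i in range(1, len(brooks)))
    cv_pass = tuple(s.cv < cv_threshold for s in stats)
    crosby_pass = tuple(abs(c) < crosby_threshold for c in crosby)
    return InstarValidationReport(
        per_instar=tuple(stats),
        brooks=brooks,
        crosby=crosby,
        cv_pass=cv_pass,
        crosby_pass=crosby_pass,
        cv_threshold=cv_threshold,
        crosby_threshold=crosby_threshold,
    )


def evaluate_criteria(
    report: InstarValidationReport,
    cv_threshold: float = 15.0,
    crosby_threshold: float = 0.1,
) -> CriteriaVerdict:
    """Re-evaluate the pass/fail criteria at the given thresholds.

    Strict inequalities: a CV of exactly the threshold fails, as does a
    Crosby magnitude of exactly the threshold. Lowering either threshold
    can only turn passes into fails, never the reverse.
    """
    cv_pass = tuple(s.cv < cv_threshold for s in report.per_instar)
    crosby_pass = tuple(abs(c) < crosby_threshold for c in report.crosby)
    return CriteriaVerdict(
        cv_pass=cv_pass,
        crosby_pass=crosby_pass,
        overall=all(cv_pass) and all(crosby_pass),
    )


def dyar_regression(
    means: Sequence[float], instars: Sequence[int] | None = None
) -> DyarRegressionResult:
    """Ordinary least squares of ln(mean HCW) on instar number.

    Under Dyar's rule the means form a geometric progression, so the log
    means are exactly linear in instar number and R² = 1. The F statistic
    (df 1, k−2) equals the squared t statistic of the slope.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("means must be > 0 for the log transform")
    k = means.size
    if k < 3:
        raise ValueError("need at least 3 instars for the regression")
    x = np.asarray(instars, dtype=float) if instars is not None else np.arange(1, k + 1.0)
    if x.size != k:
        raise ValueError("instars and means must have equal length")
    fit = sps.linregress(x, np.log(means))
    r2 = float(fit.rvalue**2)
    if math.isfinite(fit.stderr) and fit.stderr > 0:
        f_stat = float((fit.slope / fit.stderr) ** 2)
    else:  # perfect fit: infinite F, p = 0
        f_stat = math.inf
    return DyarRegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        f_stat=f_stat,
        p_value=float(fit.pvalue),
        n_points=int(k),
    )
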
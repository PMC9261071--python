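"""Decision layer: significance, biological relevance, change-point calls.

A contrast row is *significant* when its simultaneous interval excludes
zero, and *biologically relevant* when the whole interval lies beyond a
user-chosen relevance band (default +/- 1 on the log scale) — relevance is
deliberately stricter than significance, since with enough samples tiny
effects turn significant. Consecutive-interval overlap is tracked because a
change point should separate its interval from the preceding one.

Contrast-specific calls:

* Sequen rows localize change points — row "i+1 - i" significant means the
  mean moved between time points i and i+1, with the sign giving the
  direction. Adjacent significant rows with opposite signs are flagged as
  possible fluctuation rather than two clean change points.
* McDermott rows answer whether the course changed at all relative to its
  preceding history; a significant row whose interval does not overlap its
  predecessor's drives an overall-change verdict.

Also provided: a back-of-envelope bound on how many comparisons a course can
support before multiplicity adjustment swallows the largest effect. With
maximal effect delta_max and standard deviation s, z = delta_max / s gives a
best-case p-value p_max = Phi(-z) (doubled for two-sided), and a Bonferroni
argument caps the usable comparisons at floor(alpha / p_max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ContractError, DomainError
from .simci import SimultaneousCI

__all__ = [
    "RelevanceConfig",
    "ChangePointReport",
    "MaxStepsResult",
    "classify",
    "detect_changepoints_sequen",
    "overall_change_mcdermott",
    "max_usable_steps",
    "SequenChangePoint",
]


@dataclass
class RelevanceConfig:
    """Relevance band and level for the decision layer.

    ``point_estimate_mode`` relaxes the relevance rule to require only the
    point estimate (not the whole interval) beyond the band.
    """

    lower_limit: float = -1.0
    upper_limit: float = 1.0
    alpha: float = 0.05
    point_estimate_mode: bool = False

    def __post_init__(self) -> None:
        if not self.lower_limit < self.upper_limit:
            raise DomainError("lower_limit must be below upper_limit")
        if not self.lower_limit < 0.0 < self.upper_limit:
            raise DomainError("the relevance band must contain zero")


@dataclass
class ChangePointReport:
    """Classified contrast rows plus the settings that produced them."""

    rows: pd.DataFrame
    ctype: str
    config: RelevanceConfig
    singular_fit: bool = False
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


class SequenChangePoint(NamedTuple):
    time_index: int  # 1-based index of the later time point of the pair
    direction: str  # "up" or "down"
    estimate: float
    lower: float
    upper: float


class SequenResult(NamedTuple):
    changepoints: list[SequenChangePoint]
    fluctuation: bool  # adjacent significant rows with opposite signs


class McDermottResult(NamedTuple):
    changed: bool
    driving_rows: list[str]


class MaxStepsResult(NamedTuple):
    z_score: float
    p_max: float
    n_max: int
    sided: str


def classify(sci: SimultaneousCI, cfg: RelevanceConfig | None = None) -> ChangePointReport:
    """Classify each contrast row by significance, relevance and direction.

    significant: the interval excludes zero. relevant: the entire interval
    lies beyond the relevance band (point-estimate mode: the estimate does,
    and the row is significant). direction: sign of the estimate when
    significant, "none" otherwise. overlap_with_previous: overlap length of
    consecutive intervals, NaN for the first row.
    """
    cfg = cfg or RelevanceConfig()
    rows = sci.rows.copy()
    lower = rows["lower"].to_numpy()
    upper = rows["upper"].to_numpy()
    est = rows["estimate"].to_numpy()

    significant = (lower > 0) | (upper < 0)
    if cfg.point_estimate_mode:
        relevant = significant & ((est > cfg.upper_limit) | (est < cfg.lower_limit))
    else:
        relevant = (lower > cfg.upper_limit) | (upper < cfg.lower_limit)
    direction = np.where(significant, np.where(est > 0, "up", "down"), "none")

    overlap = np.full(len(rows), np.nan)
    for i in range(1, len(rows)):
        overlap[i] = max(
            0.0, min(upper[i], upper[i - 1]) - max(lower[i], lower[i - 1])
        )

    rows["significant"] = significant
    rows["relevant"] = relevant
    rows["direction"] = direction
    rows["overlap_with_previous"] = overlap
    return ChangePointReport(
        rows=rows,
        ctype=sci.ctype,
        config=cfg,
        singular_fit=sci.singular_fit,
        meta={"alpha": sci.alpha, "df": sci.df, "crit": sci.crit, "seed": sci.seed},
    )


def detect_changepoints_sequen(report: ChangePointReport) -> SequenResult:
    """Change-point positions and directions from a Sequen report.

    Returns one entry per significant row; row i ("i+1 - i") places the
    change at time index i+1 (1-based). The fluctuation flag is raised when
    successive significant rows carry opposite signs — the mean swinging
    back may be noise or a transient rather than two clean change points,
    and deserves a second look.
    """
    if report.ctype != "sequen":
        raise ContractError(f"expected a sequen report, got {report.ctype!r}")
    rows = report.rows
    cps: list[SequenChangePoint] = []
    for i, row in rows.iterrows():
        if row["significant"]:
            cps.append(
                SequenChangePoint(
                    time_index=int(i) + 2,  # row i compares t_{i+1} vs t_{i+2}
                    direction=row["direction"],
                    estimate=float(row["estimate"]),
                    lower=float(row["lower"]),
                    upper=float(row["upper"]),
                )
            )
    fluctuation = any(
        cps[j + 1].direction != cps[j].direction for j in range(len(cps) - 1)
    )
    return SequenResult(cps, fluctuation)


def overall_change_mcdermott(
    report: ChangePointReport, overlap_tolerance: float = 0.0
) -> McDermottResult:
    """Overall-change verdict from a McDermott report.

    A row drives the verdict when it is significant and its interval does
    not overlap the preceding row's interval by more than
    ``overlap_tolerance`` (the first row has no predecessor, so significance
    alone suffices there).
    """
    if report.ctype != "mcdermott":
        raise ContractError(f"expected a mcdermott report, got {report.ctype!r}")
    rows = report.rows
    driving: list[str] = []
    for i, row in rows.iterrows():
        if not row["significant"]:
            continue
        ov = row["overlap_with_previous"]
        if np.isnan(ov) or ov <= overlap_tolerance:
            driving.append(str(row["label"]))
    return McDermottResult(bool(driving), driving)


def max_usable_steps(
    delta_max: float,
    s: float,
    alpha: float = 0.05,
    sided: str = "one",
) -> MaxStepsResult:
    """Approximate cap on comparisons before multiplicity swallows the effect.

    z = delta_max / s; p_max = Phi(-|z|) one-sided or 2 Phi(-|z|) two-sided;
    n_max = floor(alpha / p_max) by a Bonferroni argument. One-sided is the
    default. This is a planning heuristic, not part of the testing machinery.
    """
    if s <= 0:
        raise DomainError(f"standard deviation must be positive, got {s}")
    if delta_max < 0:
        raise DomainError("delta_max must be nonnegative")
    if sided not in ("one", "two"):
        raise DomainError("sided must be 'one' or 'two'")
    z = delta_max / s
    p = float(stats.norm.cdf(-abs(z)))
    if sided == "two":
        p = min(1.0, 2.0 * p)
    if p > 0 and alpha / p < 9e307:
        n_max = int(math.floor(alpha / p))
    else:
        # tail beyond double precision: order of magnitude from the log tail
        log10_p = stats.norm.logsf(abs(z)) / math.log(10)
        if sided == "two":
            log10_p += math.log10(2.0)
        n_max = 10 ** int(math.floor(math.log10(alpha) - log10_p))
    return MaxStepsResult(z_score=z, p_max=p, n_max=n_max, sided=sided)
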
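"""Contrast matrices for change-point scenarios over ordered time points.

Each matrix has T columns (the time points) and T-1 rows, one per candidate
change point; every row is a zero-sum weight vector over the time-point
means, so C @ beta is a vector of interpretable mean differences. Three
constructions are provided:

* **Changepoint** — row i compares the (sample-size-weighted) mean of time
  points 1..i against the weighted mean of time points i+1..T.
* **Sequen** — row i compares time point i against time point i+1 only
  (a sequence of adjacent two-group comparisons).
* **McDermott** — row i compares the weighted mean of time points 1..i
  against time point i+1 alone; sensitive to changes relative to the whole
  preceding course.

By default weights are adjusted for unbalanced per-time-point sample sizes
(each group weight is n_j divided by the group's total n); with all-equal
sample sizes this reduces to the balanced textbook form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DomainError, SpecError

__all__ = [
    "ContrastMatrix",
    "build_changepoint",
    "build_sequen",
    "build_mcdermott",
    "build_contrast",
    "CONTRAST_TYPES",
]

CONTRAST_TYPES = ("changepoint", "sequen", "mcdermott")


@dataclass
class ContrastMatrix:
    """A (T-1) x T zero-row-sum weight matrix with row labels."""

    weights: np.ndarray
    row_labels: list[str]
    ctype: str
    n_used: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{j + 1}" for j in range(self.n_timepoints)]
        return pd.DataFrame(self.weights, index=self.row_labels, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().round(6).to_csv(path, sep="\t", index_label="contrast")


def _check_n(n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if n.ndim != 1 or len(n) < 2:
        raise SpecError("need sample sizes for at least 2 time points")
    if np.any(n <= 0):
        raise DomainError(f"sample sizes must be positive, got {n.tolist()}")
    return n


def build_changepoint(n) -> ContrastMatrix:
    """Changepoint contrast, weighted by per-time-point sample sizes ``n``.

    Row i carries -n_j / sum(n_1..n_i) for j <= i and +n_j / sum(n_{i+1}..n_T)
    for j > i, so the negative and positive weights each sum to one in
    magnitude.
    """
    n = _check_n(n)
    T = len(n)
    W = np.zeros((T - 1, T))
    for i in range(1, T):
        W[i - 1, :i] = -n[:i] / n[:i].sum()
        W[i - 1, i:] = n[i:] / n[i:].sum()
    labels = [f"C{i}" for i in range(1, T)]
    return ContrastMatrix(W, labels, "changepoint", n)


def build_sequen(T: int) -> ContrastMatrix:
    """Sequential (adjacent pairs) contrast for ``T`` time points.

    Row i has -1 at time point i and +1 at time point i+1; sample sizes play
    no role. Rows are labelled "2-1" .. "T-(T-1)" (later minus earlier).
    """
    T = int(T)
    if T < 2:
        raise SpecError("need at least 2 time points")
    W = np.zeros((T - 1, T))
    for i in range(T - 1):
        W[i, i] = -1.0
        W[i, i + 1] = 1.0
    labels = [f"{i + 2}-{i + 1}" for i in range(T - 1)]
    return ContrastMatrix(W, labels, "sequen", np.ones(T))


def build_mcdermott(n) -> ContrastMatrix:
    """McDermott contrast, weighted by per-time-point sample sizes ``n``.

    Row i carries -n_j / sum(n_1..n_i) for j <= i, exactly +1 at time point
    i+1 and zeros after it.
    """
    n = _check_n(n)
    T = len(n)
    W = np.zeros((T - 1, T))
    for i in range(1, T):
        W[i - 1, :i] = -n[:i] / n[:i].sum()
        W[i - 1, i] = 1.0
    labels = [f"C{i}" for i in range(1, T)]
    return ContrastMatrix(W, labels, "mcdermott", n)


def build_contrast(ctype: str, n, balanced: bool = False) -> ContrastMatrix:
    """Dispatch on contrast type; ``balanced`` forces all-ones weighting."""
    n = _check_n(n)
    if balanced:
        n = np.ones_like(n)
    if ctype == "changepoint":
        return build_changepoint(n)
    if ctype == "sequen":
        return build_sequen(len(n))
    if ctype == "mcdermott":
        return build_mcdermott(n)
    raise SpecError(f"unknown contrast type {ctype!r}; one of {CONTRAST_TYPES}")
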
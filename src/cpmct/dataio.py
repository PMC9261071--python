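"""Reading, validation and summaries of long-format clustered expression tables.

The workflow's input is *historical* data: one row per animal, with an
expression value, an ordered time-point label (e.g. a developmental stage)
and a cluster identifier (the mother/litter). Observations at different time
points are independent — each examination is lethal, so no animal is measured
twice — while littermates at the same time point share a mother effect. The
design is therefore *nested*: every cluster belongs to exactly one time point.

Expression values are usually analyzed on the log scale to meet the
normality assumption of the downstream linear mixed model; the natural
logarithm (base e) is used throughout, so contrast effects read as log mean
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import DomainError, InputSchemaError, NestingViolationError

__all__ = ["ExpressionDataset", "read_long_table", "summarize"]

#: canonical column order of the internal observation table
_COLUMNS = ["value", "raw_value", "timepoint", "cluster", "unit"]


@dataclass
class ExpressionDataset:
    """Validated long-format clustered expression data for one gene.

    Parameters
    ----------
    observations
        DataFrame with columns ``value`` (analysis scale, possibly
        log-transformed), ``raw_value`` (original scale; may be NaN when no
        transform was applied), ``timepoint`` (label), ``cluster``
        (mother/litter identifier) and ``unit`` (animal identifier).
    timepoint_order
        The T distinct time-point labels in chronological order; index 1..T
        in all user-facing reports.
    meta
        Free-form provenance (source file, transform applied, scenario spec).
    """

    observations: pd.DataFrame
    timepoint_order: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.observations = self.observations.reset_index(drop=True)
        self.timepoint_order = [str(t) for t in self.timepoint_order]
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        obs = self.observations
        missing = [c for c in _COLUMNS if c not in obs.columns]
        if missing:
            raise InputSchemaError(f"observation table lacks columns {missing}")
        if len(self.timepoint_order) < 2:
            raise InputSchemaError(
                f"need at least 2 time points, got {len(self.timepoint_order)}"
            )
        if len(set(self.timepoint_order)) != len(self.timepoint_order):
            raise InputSchemaError("timepoint_order contains duplicate labels")
        seen = set(obs["timepoint"].astype(str))
        extra = seen - set(self.timepoint_order)
        if extra:
            raise InputSchemaError(f"time points {sorted(extra)} not in timepoint_order")
        empty = [t for t in self.timepoint_order if t not in seen]
        if empty:
            raise InputSchemaError(f"time points {empty} have no observations")
        values = obs["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = obs.index[~np.isfinite(values)].tolist()
            raise DomainError(f"non-finite analysis-scale values at rows {bad[:5]}")
        # nested design: each cluster lives at exactly one time point
        tp_per_cluster = obs.groupby("cluster", sort=False)["timepoint"].nunique()
        offenders = tp_per_cluster[tp_per_cluster > 1]
        if len(offenders):
            raise NestingViolationError(
                "clusters observed at more than one time point: "
                f"{offenders.index.tolist()}"
            )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_order)

    @property
    def clusters(self) -> list:
        """Cluster identifiers in order of first appearance."""
        return self.observations["cluster"].drop_duplicates().tolist()

    @property
    def n_clusters(self) -> int:
        return self.observations["cluster"].nunique()

    def timepoint_index(self) -> np.ndarray:
        """0-based time-point index per observation, following timepoint_order."""
        mapping = {t: i for i, t in enumerate(self.timepoint_order)}
        return self.observations["timepoint"].astype(str).map(mapping).to_numpy()

    def n_per_timepoint(self) -> np.ndarray:
        """Observation counts per time point, in timepoint_order."""
        counts = self.observations["timepoint"].astype(str).value_counts()
        return np.array([counts[t] for t in self.timepoint_order], dtype=int)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the observation table as a tab-separated long table."""
        out = self.observations[_COLUMNS].copy()
        out.to_csv(path, sep="\t", index=False)


def _infer_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_long_table(
    path: str | Path,
    value_col: str = "value",
    timepoint_col: str = "timepoint",
    cluster_col: str = "cluster",
    unit_col: str | None = None,
    timepoint_order: Sequence[str] | None = None,
    log_transform: bool = False,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a CSV/TSV long table into a validated :class:`ExpressionDataset`.

    The delimiter is inferred from the file extension (``.csv`` → comma,
    anything else → tab) unless given explicitly. When ``timepoint_order``
    is absent, labels are ordered by first appearance in the file. With
    ``log_transform`` the natural log is applied to strictly positive raw
    values; the original values are kept in ``raw_value``.

    Raises
    ------
    InputSchemaError
        If a named column is missing.
    DomainError
        If ``log_transform`` is requested and a value is not strictly
        positive (the offending row is named), or values are missing.
    NestingViolationError
        If a cluster identifier spans two time points.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    raw = pd.read_csv(path, sep=sep)
    for col in (value_col, timepoint_col, cluster_col):
        if col not in raw.columns:
            raise InputSchemaError(
                f"column {col!r} not found in {path.name}; available: {list(raw.columns)}"
            )
    values = pd.to_numeric(raw[value_col], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        bad = np.flatnonzero(np.isnan(values))
        raise DomainError(
            f"missing or non-numeric values in column {value_col!r} at rows "
            f"{(bad + 2)[:5].tolist()} (1-based, incl. header); missing data are rejected"
        )
    if log_transform:
        nonpos = np.flatnonzero(values <= 0)
        if nonpos.size:
            raise DomainError(
                f"log transform requires strictly positive values; offending row "
                f"{nonpos[0] + 2} (1-based, incl. header) has value {values[nonpos[0]]}"
            )
        analysis = np.log(values)
        raw_values = values
    else:
        analysis = values
        raw_values = np.full_like(values, np.nan)

    if unit_col is not None and unit_col in raw.columns:
        units = raw[unit_col].astype(str)
    else:
        units = pd.Series([f"u{i + 1}" for i in range(len(raw))])

    obs = pd.DataFrame(
        {
            "value": analysis,
            "raw_value": raw_values,
            "timepoint": raw[timepoint_col].astype(str),
            "cluster": raw[cluster_col].astype(str),
            "unit": units.to_numpy(),
        }
    )
    if timepoint_order is None:
        order = obs["timepoint"].drop_duplicates().tolist()
    else:
        order = [str(t) for t in timepoint_order]
    meta = {
        "source": str(path),
        "log_transform": bool(log_transform),
        "delimiter": sep,
    }
    return ExpressionDataset(obs, order, meta)


def summarize(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-time-point summary table plus dataset totals.

    Returns a DataFrame indexed 1..T with columns ``timepoint``, ``n``,
    ``mean``, ``sd`` (NaN when n = 1) and ``n_clusters``; the totals are
    attached under ``.attrs``: N, T and the total cluster count.
    """
    obs = ds.observations
    rows = []
    for i, t in enumerate(ds.timepoint_order, start=1):
        sub = obs[obs["timepoint"].astype(str) == t]
        v = sub["value"].to_numpy(dtype=float)
        rows.append(
            {
                "index": i,
                "timepoint": t,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "n_clusters": sub["cluster"].nunique(),
            }
        )
    table = pd.DataFrame(rows).set_index("index")
    table.attrs["N"] = int(ds.n_obs)
    table.attrs["T"] = int(ds.n_timepoints)
    table.attrs["total_clusters"] = int(ds.n_clusters)
    return table
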
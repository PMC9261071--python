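"""Clustered historical expression data simulator.

Emulates the nested design of a mouse developmental study: at each of T time
points a fresh set of mother animals is examined (the examination is lethal,
so time points are independent), every mother contributes a litter of pups,
and littermates share their mother's random effect. The generative model per
time point t is

    u_j ~ Normal(0, mother_var)                      mother effect, j = 1..m
    k_j ~ zero-truncated Poisson(litter_lambda)      litter size
    y_ij ~ Normal(mu_t + u_j, pup_var)               pup value, i = 1..k_j

with defaults of 12 time points, 3 mothers per time point, mother variance 5,
pup variance 2 and litter rate lambda = 10 (about 10 pups per litter).

The scenario library covers the mean-course shapes relevant for change-point
detection: a flat course, steady (linear) drift, stepwise jumps, a transient
drop that recovers, and a block of time points with no expression at all
(exact zeros with no variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from ._errors import SpecError
from .dataio import ExpressionDataset

__all__ = [
    "SCENARIO_KINDS",
    "ScenarioSpec",
    "timepoint_means",
    "simulate_dataset",
    "zero_truncated_poisson",
]

SCENARIO_KINDS = (
    "no_change",
    "steady_increase",
    "steady_decrease",
    "stepwise_increase",
    "stepwise_decrease",
    "partly_dropped",
    "dropped_to_zero",
)

#: default change positions (1-based) for the stepwise scenarios, by number
#: of change points; interior positions spread over the course
_DEFAULT_STEP_POSITIONS = {1: (7,), 2: (5, 9), 3: (4, 7, 10)}
#: default drop block for the transient-drop scenarios
_DEFAULT_PARTLY_DROP_BLOCK = (6, 7)
_DEFAULT_ZERO_BLOCK = (5, 6, 7, 8)


@dataclass
class ScenarioSpec:
    """Parameterization of one simulated historical expression course.

    ``changepoint_positions`` are 1-based time indices where the mean first
    takes its new level (stepwise kinds). ``drop_block`` is the contiguous
    1-based block of lowered (or zeroed) time points for the dropped kinds.
    Both have scenario defaults; see module docstring for the noise model.
    """

    kind: str = "no_change"
    n_changepoints: int | None = None
    baseline: float = 20.0
    effect: float = 10.0
    T: int = 12
    mothers_per_timepoint: int = 3
    mother_var: float = 5.0
    pup_var: float = 2.0
    litter_lambda: float = 10.0
    changepoint_positions: tuple[int, ...] | None = None
    drop_block: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise SpecError(f"unknown scenario kind {self.kind!r}; one of {SCENARIO_KINDS}")
        if self.T < 2:
            raise SpecError("T must be at least 2")
        if self.mother_var < 0 or self.pup_var < 0:
            raise SpecError("variances must be nonnegative")
        if self.litter_lambda <= 0:
            raise SpecError("litter_lambda must be positive")
        if self.mothers_per_timepoint < 1:
            raise SpecError("need at least one mother per time point")
        if self.kind in ("stepwise_increase", "stepwise_decrease"):
            if self.changepoint_positions is None:
                k = self.n_changepoints if self.n_changepoints is not None else 2
                if k not in _DEFAULT_STEP_POSITIONS:
                    raise SpecError("n_changepoints must be 1, 2 or 3")
                self.changepoint_positions = _DEFAULT_STEP_POSITIONS[k]
            self.changepoint_positions = tuple(int(p) for p in self.changepoint_positions)
            self.n_changepoints = len(self.changepoint_positions)
            pos = self.changepoint_positions
            if any(p < 2 or p > self.T for p in pos) or list(pos) != sorted(set(pos)):
                raise SpecError(
                    f"changepoint_positions must be strictly increasing within 2..T, got {pos}"
                )
        if self.kind in ("partly_dropped", "dropped_to_zero"):
            if self.drop_block is None:
                self.drop_block = (
                    _DEFAULT_PARTLY_DROP_BLOCK
                    if self.kind == "partly_dropped"
                    else _DEFAULT_ZERO_BLOCK
                )
            self.drop_block = tuple(int(p) for p in self.drop_block)
            blk = self.drop_block
            if any(p < 2 or p > self.T for p in blk) or list(blk) != list(
                range(blk[0], blk[-1] + 1)
            ):
                raise SpecError(f"drop_block must be a contiguous block within 2..T, got {blk}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("changepoint_positions", "drop_block"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        for key in ("changepoint_positions", "drop_block"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def timepoint_means(spec: ScenarioSpec) -> np.ndarray:
    """True mean expression per time point for a scenario.

    no_change: constant at ``baseline``. steady_*: linear course from
    ``baseline`` to ``baseline ± effect`` over the T points. stepwise_*:
    piecewise constant, jumping by ``±effect`` at each change position.
    partly_dropped: baseline lowered by ``effect`` over the drop block and
    restored after it. dropped_to_zero: baseline with exact zeros over the
    block.
    """
    T, b, e = spec.T, spec.baseline, spec.effect
    if spec.kind == "no_change":
        return np.full(T, b, dtype=float)
    if spec.kind in ("steady_increase", "steady_decrease"):
        sign = 1.0 if spec.kind == "steady_increase" else -1.0
        return np.linspace(b, b + sign * e, T)
    if spec.kind in ("stepwise_increase", "stepwise_decrease"):
        sign = 1.0 if spec.kind == "stepwise_increase" else -1.0
        mu = np.full(T, b, dtype=float)
        for p in spec.changepoint_positions:
            mu[p - 1 :] += sign * e
        return mu
    if spec.kind == "partly_dropped":
        mu = np.full(T, b, dtype=float)
        for p in spec.drop_block:
            mu[p - 1] = b - e
        return mu
    if spec.kind == "dropped_to_zero":
        mu = np.full(T, b, dtype=float)
        for p in spec.drop_block:
            mu[p - 1] = 0.0
        return mu
    raise SpecError(f"unknown scenario kind {spec.kind!r}")  # pragma: no cover


def zero_truncated_poisson(
    rng: np.random.Generator, lam: float, size: int
) -> np.ndarray:
    """Sample litter sizes from a Poisson conditioned on being >= 1.

    Sampled by rejection of zeros; at lambda = 10 the zero probability is
    e^-10 ~ 4.5e-5, so rejection is negligible.
    """
    if lam <= 0:
        raise SpecError("lambda must be positive")
    out = rng.poisson(lam, size=size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def simulate_dataset(spec: ScenarioSpec) -> ExpressionDataset:
    """Draw one clustered dataset under ``spec``.

    Deterministic for a fixed ``spec.seed`` (one RNG stream consumed in time
    order). Cluster identifiers (``t{t}_m{j}``) are unique across the run.
    Time points inside a ``dropped_to_zero`` block carry exact zeros for
    every pup — no expression, hence no mother effect and no noise.
    """
    rng = np.random.default_rng(spec.seed)
    mu = timepoint_means(spec)
    zero_block = set(spec.drop_block or ()) if spec.kind == "dropped_to_zero" else set()

    records: list[tuple[float, str, str, str]] = []
    for t in range(1, spec.T + 1):
        u = rng.normal(0.0, np.sqrt(spec.mother_var), size=spec.mothers_per_timepoint)
        sizes = zero_truncated_poisson(rng, spec.litter_lambda, spec.mothers_per_timepoint)
        for j in range(spec.mothers_per_timepoint):
            cluster = f"t{t}_m{j + 1}"
            if t in zero_block:
                pup_values = np.zeros(sizes[j])
            else:
                pup_values = rng.normal(
                    mu[t - 1] + u[j], np.sqrt(spec.pup_var), size=sizes[j]
                )
            for i, v in enumerate(pup_values, start=1):
                records.append((float(v), f"t{t}", cluster, f"{cluster}_p{i}"))

    obs = pd.DataFrame(records, columns=["value", "timepoint", "cluster", "unit"])
    obs.insert(1, "raw_value", np.nan)
    order = [f"t{t}" for t in range(1, spec.T + 1)]
    meta = {"scenario": spec.to_dict(), "true_means": mu.tolist()}
    return ExpressionDataset(obs, order, meta)


def variance_robustness_grid(
    base: ScenarioSpec, mother_vars: Iterable[float] = (2.0, 6.0, 10.0)
) -> list[ScenarioSpec]:
    """Specs for a small robustness study varying the mother variance.

    Sub-seeds are derived deterministically from the base seed so the grid
    is reproducible from one integer.
    """
    specs = []
    for i, mv in enumerate(mother_vars):
        d = base.to_dict()
        d["mother_var"] = float(mv)
        d["seed"] = (base.seed * 1000 + 7 * i + 1) % (2**31)
        specs.append(ScenarioSpec.from_dict(d))
    return specs
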
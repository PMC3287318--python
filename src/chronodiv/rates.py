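"""Speciation-rate functions λ(t) for time-dependent pure-birth models.

Four parametric families are supported:

* ``ConstantRate`` — a single rate λ.
* ``PiecewiseRate`` — piecewise-constant rates with breakpoint ages
  (oldest epoch first; an event exactly at a boundary age belongs to the
  younger epoch).
* ``LogisticRate`` — λ(t) = 1 / (1 + exp(-(a·t + b))) with t = time since
  the root, so a < 0 gives a rate that declines toward the present.
* ``CovariateStepRate`` — two rates keyed to an external step covariate,
  here intervals of high sea level (λ_high inside high-stand intervals,
  λ_low elsewhere).

All families expose the same small surface: ``rate_at``, ``max_rate``,
``boundary_ages`` (for families constant within age epochs) and, for the
logistic family, an exact integral primitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "ConstantRate",
    "PiecewiseRate",
    "LogisticRate",
    "CovariateStepRate",
    "SeaLevelIntervals",
    "rate_at",
]


def _check_t(t: float, root_age: float) -> None:
    if t < -1e-12 or t > root_age + 1e-9:
        raise DomainError(f"t={t} outside [0, root_age={root_age}]")


@dataclass(frozen=True)
class ConstantRate:
    """Constant speciation rate λ (events / lineage / Myr)."""

    rate: float

    family = "constant"

    def __post_init__(self):
        if self.rate < 0:
            raise DomainError("rate must be >= 0")

    def rate_at(self, t: float, root_age: float) -> float:
        _check_t(t, root_age)
        return self.rate

    def max_rate(self, root_age: float) -> float:
        return self.rate

    def boundary_ages(self, root_age: float) -> list[float]:
        return []

    def rate_in_age_epoch(self, old_age: float, young_age: float) -> float:
        return self.rate


@dataclass(frozen=True)
class PiecewiseRate:
    """Piecewise-constant rates with strictly decreasing breakpoint ages.

    ``rates[0]`` applies to the oldest epoch (ages above ``breakpoint_ages[0]``),
    ``rates[-1]`` to the youngest.  Epochs are half-open: an event exactly at a
    breakpoint age belongs to the younger epoch.
    """

    rates: tuple[float, ...]
    breakpoint_ages: tuple[float, ...]

    family = "piecewise"

    def __post_init__(self):
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        object.__setattr__(
            self, "breakpoint_ages", tuple(float(b) for b in self.breakpoint_ages)
        )
        if any(r < 0 for r in self.rates):
            raise DomainError("rates must be >= 0")
        if len(self.rates) != len(self.breakpoint_ages) + 1:
            raise DomainError("need exactly one more rate than breakpoints")
        bp = self.breakpoint_ages
        if any(bp[i] <= bp[i + 1] for i in range(len(bp) - 1)):
            raise DomainError("breakpoint ages must be strictly decreasing")
        if any(b <= 0 for b in bp):
            raise DomainError("breakpoint ages must be positive")

    def _epoch_of_age(self, age: float) -> int:
        # epoch j covers ages (bp[j], bp[j-1]]; age == bp[j] -> younger epoch
        j = 0
        for b in self.breakpoint_ages:
            if age > b:
                return j
            j += 1
        return j

    def rate_at(self, t: float, root_age: float) -> float:
        _check_t(t, root_age)
        return self.rates[self._epoch_of_age(root_age - t)]

    def max_rate(self, root_age: float) -> float:
        return max(self.rates)

    def boundary_ages(self, root_age: float) -> list[float]:
        return [b for b in self.breakpoint_ages if 0 < b < root_age]

    def rate_in_age_epoch(self, old_age: float, young_age: float) -> float:
        mid = 0.5 * (old_age + young_age)
        return self.rates[self._epoch_of_age(mid)]


@dataclass(frozen=True)
class LogisticRate:
    """Sigmoid rate λ(t) = 1/(1 + exp(-(a t + b))), t measured since the root.

    Bounded in (0, 1); a < 0 yields a slowdown toward the present.
    """

    a: float
    b: float

    family = "logistic"

    def rate_at(self, t: float, root_age: float) -> float:
        _check_t(t, root_age)
        return float(_sigmoid(self.a * t + self.b))

    def max_rate(self, root_age: float) -> float:
        # monotone in t, so the supremum is at an endpoint
        if self.a == 0.0 or not np.isfinite(root_age):
            end = _sigmoid(self.b) if self.a == 0.0 else (1.0 if self.a > 0 else 0.0)
        else:
            end = _sigmoid(self.a * root_age + self.b)
        return max(float(_sigmoid(self.b)), float(end))

    def integral(self, t0: float, t1: float) -> float:
        """Integral of λ(t) dt over [t0, t1] (softplus primitive).

        For |a|·(t1-t0) below 1e-6 the primitive difference cancels
        catastrophically, so a midpoint evaluation (error O((aΔt)²)) is
        used instead.
        """
        a, b = self.a, self.b
        dt = t1 - t0
        if abs(a * dt) < 1e-6:
            return float(_sigmoid(a * 0.5 * (t0 + t1) + b)) * dt
        return float((_softplus(a * t1 + b) - _softplus(a * t0 + b)) / a)


@dataclass(frozen=True)
class SeaLevelIntervals:
    """Closed age intervals [start_age, end_age] flagged as high sea level.

    Ages decrease toward the present, so ``start_age > end_age`` within each
    interval.  Overlapping or touching intervals are merged on construction.
    """

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        norm = []
        for s, e in self.intervals:
            s, e = float(s), float(e)
            if s <= e:
                raise DomainError(
                    f"interval ({s}, {e}): start_age must exceed end_age"
                )
            if e < 0:
                raise DomainError("interval ages must be >= 0")
            norm.append((s, e))
        norm.sort(key=lambda x: -x[0])  # oldest first
        merged: list[list[float]] = []
        for s, e in norm:  # oldest start first
            if merged and s >= merged[-1][1]:  # overlaps/touches previous interval
                merged[-1][1] = min(merged[-1][1], e)
            else:
                merged.append([s, e])
        object.__setattr__(self, "intervals", tuple((s, e) for s, e in merged))

    def is_high(self, age: float) -> bool:
        return any(e <= age <= s for s, e in self.intervals)

    def boundary_ages(self) -> list[float]:
        out = []
        for s, e in self.intervals:
            out.extend([s, e])
        return sorted({a for a in out if a > 0}, reverse=True)

    @classmethod
    def from_csv(cls, path) -> "SeaLevelIntervals":
        """Two-column comma-separated file ``start_age,end_age``, one per row."""
        import pandas as pd

        df = pd.read_csv(path, header=None, comment="#")
        if df.shape[1] < 2:
            raise DomainError("interval file needs two columns: start_age,end_age")
        # tolerate a header row
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        pairs = [(float(r[0]), float(r[1])) for r in df.itertuples(index=False)]
        return cls(tuple(pairs))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{s},{e}\n")


@dataclass(frozen=True)
class CovariateStepRate:
    """Two-rate model keyed to high/low sea-level stands.

    ``rate_high`` applies inside the high-stand age intervals, ``rate_low``
    elsewhere (including all ages older than the covariate record).
    """

    rate_high: float
    rate_low: float
    intervals: SeaLevelIntervals

    family = "covariate_step"

    def __post_init__(self):
        if self.rate_high < 0 or self.rate_low < 0:
            raise DomainError("rates must be >= 0")

    def rate_at(self, t: float, root_age: float) -> float:
        _check_t(t, root_age)
        age = root_age - t
        return self.rate_high if self.intervals.is_high(age) else self.rate_low

    def max_rate(self, root_age: float) -> float:
        return max(self.rate_high, self.rate_low)

    def boundary_ages(self, root_age: float) -> list[float]:
        return [a for a in self.intervals.boundary_ages() if 0 < a < root_age]

    def rate_in_age_epoch(self, old_age: float, young_age: float) -> float:
        mid = 0.5 * (old_age + young_age)
        return self.rate_high if self.intervals.is_high(mid) else self.rate_low


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus(x):
    return np.logaddexp(0.0, x)


def rate_at(model, t: float, root_age: float) -> float:
    """Evaluate λ(t) for any rate family (t = Myr since the root)."""
    return model.rate_at(t, root_age)
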
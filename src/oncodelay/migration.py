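"""Cumulative stage-migration probability as a function of diagnostic delay.

A :class:`MigrationCurve` carries the cumulative probability that a tumour
has migrated (advanced one TNM stage) by a given delay, anchored at the
published 1/3/6/12-month probabilities and pinned to zero at delay zero.
Between anchors the curve is interpolated — piecewise linearly by default,
or with a geometric per-month progression model as an alternative — and is
held constant beyond the last anchor.

From a curve the module locates the *critical delay threshold* (the first
integer day at which the migration probability reaches a level, 10% by
default) and the number needed to treat (NNT): how many patients would need
an expedited diagnostic pathway to prevent one stage migration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params

__all__ = [
    "MigrationCurve",
    "ThresholdResult",
    "build_curve",
    "migration_at",
    "critical_threshold",
    "nnt",
    "migration_grid",
    "default_curves",
    "curves_to_csv",
    "curves_from_csv",
]


@dataclass(frozen=True)
class MigrationCurve:
    """Nondecreasing cumulative migration probability vs. delay.

    Parameters
    ----------
    group
        Label of the stage transition, molecular class, or age band.
    anchors
        Ordered ``(time_months, probability)`` pairs starting at ``(0, 0)``.
    scheme
        ``"linear"`` for piecewise-linear interpolation between anchors, or
        ``"geometric"`` for a constant per-month survival-of-migration model
        calibrated to the one-month anchor.
    """

    group: str
    anchors: tuple[tuple[float, float], ...]
    scheme: str = "linear"

    @property
    def times_days(self) -> np.ndarray:
        return np.array([t * params.DAYS_PER_MONTH for t, _ in self.anchors])

    @property
    def probs(self) -> np.ndarray:
        return np.array([p for _, p in self.anchors])


@dataclass(frozen=True)
class ThresholdResult:
    """Critical-delay threshold and NNT for one patient group."""

    group: str
    threshold_days: int | None
    level: float = params.MIGRATION_THRESHOLD_LEVEL
    nnt: int | None = None
    printed_threshold_days: int | None = field(default=None)
    printed_nnt: int | None = field(default=None)


def build_curve(
    group: str,
    anchors: "list[tuple[float, float]] | tuple[tuple[float, float], ...]",
    scheme: str = "linear",
) -> MigrationCurve:
    """Validate anchors and return a :class:`MigrationCurve`.

    A ``(0, 0)`` origin anchor is prepended when absent.  Times must be
    strictly increasing and probabilities nondecreasing within [0, 1].
    """
    anchors = [(float(t), float(p)) for t, p in anchors]
    if not anchors or anchors[0] != (0.0, 0.0):
        anchors = [(0.0, 0.0)] + anchors
    times = [t for t, _ in anchors]
    probs = [p for _, p in anchors]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError(f"{group}: anchor times must be strictly increasing")
    if any(p1 > p2 for p1, p2 in zip(probs, probs[1:])):
        raise ValueError(f"{group}: anchor probabilities must be nondecreasing")
    if probs[-1] > 1.0 or min(probs) < 0.0:
        raise ValueError(f"{group}: probabilities must lie in [0, 1]")
    if scheme not in ("linear", "geometric"):
        raise ValueError(f"unknown interpolation scheme {scheme!r}")
    return MigrationCurve(group=group, anchors=tuple(anchors), scheme=scheme)


def migration_at(curve: MigrationCurve, delay_days: float) -> float:
    """Cumulative migration probability after ``delay_days`` of delay.

    Linear scheme: piecewise-linear interpolation between anchors (months
    converted at 30 days/month) with constant extrapolation past the last
    anchor.  Geometric scheme: ``1 - (1 - p1)**(d/30)`` with ``p1`` the
    one-month anchor, capped at the last anchor's value.
    """
    if delay_days < 0:
        raise ValueError("delay must be nonnegative")
    if len(curve.anchors) == 1:  # origin only: identically zero
        return 0.0
    if curve.scheme == "geometric":
        p1 = curve.anchors[1][1] if curve.anchors[1][0] == 1.0 else None
        if p1 is None:
            raise ValueError("geometric scheme requires a 1-month anchor")
        p = 1.0 - (1.0 - p1) ** (delay_days / params.DAYS_PER_MONTH)
        return min(p, float(curve.probs[-1]))
    return float(np.interp(delay_days, curve.times_days, curve.probs))


def critical_threshold(
    curve: MigrationCurve,
    level: float = params.MIGRATION_THRESHOLD_LEVEL,
    max_days: int = 2 * params.DAYS_PER_YEAR,
) -> ThresholdResult:
    """Smallest integer day at which the curve reaches ``level``.

    Scans day by day; returns ``threshold_days=None`` when the curve never
    reaches the level within ``max_days``.  The published reference
    threshold and NNT for the group, when known, ride along for reporting.

    The NNT treats the three-month migration probability as the absolute
    risk an expedited pathway removes (an expedited work-up replaces a
    typical one-quarter diagnostic interval with a near-immediate one).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    threshold = None
    for day in range(max_days + 1):
        if migration_at(curve, day) >= level:
            threshold = day
            break
    arr = migration_at(curve, 3 * params.DAYS_PER_MONTH)
    n = nnt(arr) if arr > 0 else None
    return ThresholdResult(
        group=curve.group,
        threshold_days=threshold,
        level=level,
        nnt=n,
        printed_threshold_days=params.PRINTED_THRESHOLD_DAYS.get(curve.group),
        printed_nnt=params.PRINTED_NNT.get(curve.group),
    )


def nnt(absolute_risk_reduction: float) -> int:
    """Number needed to treat: ``ceil(1 / ARR)`` for ARR in (0, 1]."""
    if not 0.0 < absolute_risk_reduction <= 1.0:
        raise ValueError("absolute risk reduction must lie in (0, 1]")
    return math.ceil(1.0 / absolute_risk_reduction)


def migration_grid(
    curves: dict[str, MigrationCurve],
    categories: "list[str] | None" = None,
) -> pd.DataFrame:
    """Evaluate every curve at each delay category's representative day.

    Returns a DataFrame indexed by curve group with one column per delay
    category; the reference category column is zero by construction.
    """
    if categories is None:
        categories = list(params.DELAY_LABELS)
    rows = {}
    for group, curve in curves.items():
        row = {}
        for cat in categories:
            if cat not in params.DELAY_REPRESENTATIVE_DAYS:
                raise KeyError(f"unknown delay category {cat!r}")
            day = params.DELAY_REPRESENTATIVE_DAYS[cat]
            row[cat] = 0.0 if day == 0 else migration_at(curve, day)
        rows[group] = row
    if not rows:
        raise ValueError("no curves supplied")
    return pd.DataFrame.from_dict(rows, orient="index")[categories]


def default_curves(scheme: str = "linear") -> dict[str, MigrationCurve]:
    """The published anchor set as ready-made curves."""
    return {
        group: build_curve(group, list(anchors), scheme=scheme)
        for group, anchors in params.MIGRATION_ANCHORS.items()
    }


def curves_to_csv(curves: dict[str, MigrationCurve], path) -> None:
    """Write curves as a (group, month, probability) parameter file."""
    records = [
        {"group": c.group, "month": t, "probability": p}
        for c in curves.values()
        for t, p in c.anchors
        if t > 0
    ]
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def curves_from_csv(path, scheme: str = "linear") -> dict[str, MigrationCurve]:
    """Read a (group, month, probability) parameter file."""
    df = pd.read_csv(path)
    curves = {}
    for group, sub in df.groupby("group", sort=False):
        anchors = sorted(zip(sub["month"], sub["probability"]))
        curves[group] = build_curve(str(group), anchors, scheme=scheme)
    return curves
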
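"""Corridor-of-stability metrics and required-sample-size tables.

Four stability criteria are aggregated across replications at each sample
size n:

``sign_correct``
    The point estimate is above zero (guards against Type S errors when
    the population correlation is positive).
``robust_nonzero``
    The lower bound of the 66/90/95% interval is above zero (the Bayesian
    analogue of statistical power).
``estimate_in_cos``
    The point estimate lies inside the corridor of stability (COS), an
    interval around the population correlation rho (guards against Type M
    errors).
``interval_in_cos``
    The whole interval lies inside the COS (a precision requirement).

The corridor of half-width ``w`` is ``rho +/- w`` on the correlation
scale by default, following the original corridor-of-stability
construction.  A variant symmetric in Fisher-z space (``w`` read in
Cohen's q units, corridor ``tanh(atanh(rho) +/- w)``) is available via
``scale="z"``; for the widths studied here the two differ by less than
0.02 in the bounds.

The required sample size for threshold P is the smallest evaluated n at
which the across-replication proportion reaches P (first-crossing rule;
the curve may dip below P again afterwards).  A sustained-crossing variant
is available.  Results at the grid boundaries are censored and rendered
as "< n_min" / "> n_max".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import BatchEstimates

__all__ = [
    "COSSpec",
    "ProportionCurve",
    "RequiredN",
    "CRITERIA",
    "cos_bounds",
    "proportion_curve",
    "required_n",
    "build_tables",
    "curves_to_frame",
    "frame_to_curves",
]

CRITERIA = ("sign_correct", "robust_nonzero", "estimate_in_cos", "interval_in_cos")


@dataclass(frozen=True)
class COSSpec:
    """Corridor of stability around one population correlation."""

    rho: float
    w: float
    lower: float
    upper: float
    scale: str = "raw"

    def __post_init__(self) -> None:
        if not -1.0 < self.lower < self.rho < self.upper < 1.0:
            raise ValueError(
                f"COS bounds must satisfy -1 < lower < rho < upper < 1, "
                f"got ({self.lower}, {self.rho}, {self.upper})"
            )


def cos_bounds(rho: float, w: float, scale: str = "raw") -> COSSpec:
    """Corridor of stability of half-width ``w`` around ``rho``.

    ``scale="raw"`` (default) uses ``rho +/- w`` on the correlation scale,
    clipped to (-1, 1); ``scale="z"`` places the corridor symmetrically in
    Fisher-z space (``w`` in Cohen's q units).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    if w <= 0:
        raise ValueError(f"w must be positive, got {w}")
    if scale == "z":
        z = math.atanh(rho)
        lower, upper = math.tanh(z - w), math.tanh(z + w)
    elif scale == "raw":
        lower, upper = max(rho - w, -1.0 + 1e-12), min(rho + w, 1.0 - 1e-12)
    else:
        raise ValueError(f"unknown COS scale {scale!r}")
    return COSSpec(rho=rho, w=w, lower=lower, upper=upper, scale=scale)


@dataclass(frozen=True)
class ProportionCurve:
    """One aggregated proportion as a function of n."""

    criterion: str
    points: dict[int, float]
    n_reps: int
    model_tag: str
    rho: float
    level: float | None = None
    w: float | None = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for n, p in self.points.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion {p} at n={n} outside [0, 1]")

    def ns(self) -> np.ndarray:
        return np.asarray(sorted(self.points))

    def proportions(self) -> np.ndarray:
        return np.asarray([self.points[n] for n in sorted(self.points)])


def proportion_curve(
    estimates: BatchEstimates,
    criterion: str,
    level: float | None = None,
    cos: COSSpec | None = None,
) -> ProportionCurve:
    """Across-replication proportion meeting one criterion at each n.

    ``level`` is required for interval-based criteria; ``cos`` for
    COS-based criteria.  Replications with undefined estimates (NaN) at a
    given n are excluded from that n's denominator.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    point = estimates.point
    if criterion == "sign_correct":
        ok = point > 0
        valid = np.isfinite(point)
    elif criterion == "robust_nonzero":
        if level is None:
            raise ValueError("robust_nonzero needs an interval level")
        lo, _ = estimates.intervals[level]
        ok = lo > 0
        valid = np.isfinite(lo)
    elif criterion == "estimate_in_cos":
        if cos is None:
            raise ValueError("estimate_in_cos needs a COSSpec")
        ok = (point >= cos.lower) & (point <= cos.upper)
        valid = np.isfinite(point)
    else:  # interval_in_cos
        if cos is None or level is None:
            raise ValueError("interval_in_cos needs a COSSpec and a level")
        lo, hi = estimates.intervals[level]
        ok = (lo >= cos.lower) & (hi <= cos.upper)
        valid = np.isfinite(lo) & np.isfinite(hi)
    denom = valid.sum(axis=0)
    if np.any(denom == 0):
        raise ValueError("no valid replications at some n")
    props = (ok & valid).sum(axis=0) / denom
    return ProportionCurve(
        criterion=criterion,
        points={int(n): float(p) for n, p in zip(estimates.n_grid, props)},
        n_reps=estimates.n_reps,
        model_tag=estimates.model_tag,
        rho=estimates.rho,
        level=level,
        w=None if cos is None else cos.w,
    )


@dataclass(frozen=True)
class RequiredN:
    """Smallest evaluated n meeting a probability threshold, with censoring.

    ``flag`` is None when uncensored, ``"below_min"`` when the threshold is
    already met at the smallest evaluated n, ``"above_max"`` when it is
    never met.  ``proportion``/``se`` report the crossing-point proportion
    and its binomial standard error (so scaled-down runs stay
    interpretable).
    """

    n: int | None
    flag: str | None
    rendered: str
    proportion: float | None = None
    se: float | None = None

    @property
    def censored(self) -> bool:
        return self.flag is not None

    def bound(self) -> int:
        """The numeric value, falling back to the censoring boundary."""
        if self.n is not None:
            return self.n
        raise ValueError(f"censored result ({self.rendered}) has no n")


def required_n(curve: ProportionCurve, P: float, rule: str = "first") -> RequiredN:
    """First (or sustained) crossing of threshold ``P`` on a proportion curve."""
    if not 0.0 < P < 1.0:
        raise ValueError(f"P must be in (0, 1), got {P}")
    if rule not in ("first", "sustained"):
        raise ValueError(f"unknown rule {rule!r}")
    ns = curve.ns()
    if ns.size == 0:
        raise ValueError("empty proportion curve")
    props = curve.proportions()
    meets = props >= P
    if rule == "sustained":
        meets = np.logical_and.accumulate(meets[::-1])[::-1]
    if not meets.any():
        return RequiredN(n=None, flag="above_max", rendered=f"> {ns[-1]}")
    j = int(np.argmax(meets))
    se = math.sqrt(props[j] * (1.0 - props[j]) / curve.n_reps)
    if j == 0:
        return RequiredN(
            n=None,
            flag="below_min",
            rendered=f"< {ns[0]}",
            proportion=float(props[0]),
            se=se,
        )
    return RequiredN(
        n=int(ns[j]),
        flag=None,
        rendered=str(int(ns[j])),
        proportion=float(props[j]),
        se=se,
    )


def curves_to_frame(curves: Iterable[ProportionCurve]) -> pd.DataFrame:
    """Long-format frame: rho, model, criterion, level, w, n, proportion, n_reps."""
    rows = []
    for c in curves:
        for n in sorted(c.points):
            rows.append(
                {
                    "rho": c.rho,
                    "model": c.model_tag,
                    "criterion": c.criterion,
                    "level": c.level,
                    "w": c.w,
                    "n": n,
                    "proportion": c.points[n],
                    "n_reps": c.n_reps,
                }
            )
    return pd.DataFrame(rows)


def frame_to_curves(frame: pd.DataFrame) -> list[ProportionCurve]:
    """Rebuild ProportionCurve objects from a long-format frame."""
    curves = []
    keys = ["rho", "model", "criterion", "level", "w"]
    frame = frame.copy()
    for col in ("level", "w"):
        frame[col] = frame[col].astype(object).where(frame[col].notna(), None)
    for key, grp in frame.groupby(keys, dropna=False, sort=True):
        rho, model, criterion, level, w = key
        curves.append(
            ProportionCurve(
                criterion=str(criterion),
                points={int(n): float(p) for n, p in zip(grp["n"], grp["proportion"])},
                n_reps=int(grp["n_reps"].iloc[0]),
                model_tag=str(model),
                rho=float(rho),
                level=None if pd.isna(level) else float(level),
                w=None if pd.isna(w) else float(w),
            )
        )
    return curves


def build_tables(
    curves: Iterable[ProportionCurve],
    p_list: Sequence[float] = (0.80, 0.90, 0.95),
    rule: str = "first",
    reference_model: str = "frequentist",
) -> pd.DataFrame:
    """Required-sample-size table over every (rho, model, criterion, P, level, w) cell.

    Each row carries the required n (or censoring flag), the crossing-point
    proportion with its binomial standard error, and the percent change
    relative to the reference model, ``(n_model - n_ref) / n_ref``, where
    both cells are uncensored.
    """
    curves = list(curves)
    rows = []
    for c in curves:
        for P in p_list:
            req = required_n(c, P, rule=rule)
            rows.append(
                {
                    "rho": c.rho,
                    "model": c.model_tag,
                    "criterion": c.criterion,
                    "level": c.level,
                    "w": c.w,
                    "P": P,
                    "required_n": req.n,
                    "censored": req.flag,
                    "rendered": req.rendered,
                    "proportion_at_n": req.proportion,
                    "binomial_se": req.se,
                    "n_reps": c.n_reps,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    cell_keys = ["rho", "criterion", "level", "w", "P"]

    def cell_key(row):
        # level/w may be None (e.g. sign_correct has no interval level);
        # normalize so missing fields compare equal across rows.
        return tuple(
            None if row[k] is None or pd.isna(row[k]) else row[k]
            for k in cell_keys
        )

    ref = {
        cell_key(row): row["required_n"]
        for _, row in table[table["model"] == reference_model].iterrows()
    }

    def pct(row):
        if row["model"] == reference_model or row["required_n"] is None:
            return None
        ref_n = ref.get(cell_key(row))
        if ref_n is None or pd.isna(ref_n):
            return None
        return (row["required_n"] - ref_n) / ref_n

    table["pct_change_vs_reference"] = table.apply(pct, axis=1)

    def render_pct(v):
        if v is None or pd.isna(v):
            return ""
        return f"{v:+.0%}"

    table["pct_rendered"] = table["pct_change_vs_reference"].map(render_pct)
    return table
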
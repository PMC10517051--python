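"""Prefix Pearson correlations and Fisher-z confidence intervals.

Correlation trajectories are computed incrementally from running sums, so
a whole batch of 10,000 trajectories over n = 10..500 costs a handful of
cumulative-sum passes.  Confidence intervals use the Fisher
z-transformation: with z = atanh(r) approximately normal with standard
error 1/sqrt(n - 3), the level-L interval is
tanh(atanh(r) +/- q_{(1+L)/2} / sqrt(n - 3)).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datagen import TrajectoryBatch
from .records import BatchEstimates, EstimateRecord

__all__ = [
    "prefix_pearson",
    "fisher_interval",
    "estimate_trajectory_frequentist",
    "estimate_batch_frequentist",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS: tuple[float, ...] = (0.66, 0.90, 0.95)


def prefix_pearson(stream: np.ndarray, n_min: int = 10) -> np.ndarray:
    """Sample correlation of every prefix of an (x, y) stream.

    Parameters
    ----------
    stream
        Array of shape ``(..., n_max, 2)``; leading axes (e.g. replications)
        are vectorized over.
    n_min
        Smallest prefix length evaluated (must be >= 3).

    Returns
    -------
    Array of shape ``(..., n_max - n_min + 1)`` holding ``r_n`` for
    ``n = n_min .. n_max``.  Prefixes with zero variance in x or y yield
    NaN (with a warning) and are excluded from downstream aggregation.
    """
    stream = np.asarray(stream, dtype=float)
    if stream.shape[-1] != 2:
        raise ValueError("stream must have trailing dimension 2 (x, y pairs)")
    if n_min < 3:
        raise ValueError(f"n_min must be >= 3, got {n_min}")
    n_max = stream.shape[-2]
    if n_min > n_max:
        raise ValueError(f"n_min={n_min} exceeds stream length {n_max}")
    x = stream[..., 0]
    y = stream[..., 1]
    n = np.arange(1, n_max + 1, dtype=float)
    sx = np.cumsum(x, axis=-1)
    sy = np.cumsum(y, axis=-1)
    sxx = np.cumsum(x * x, axis=-1)
    syy = np.cumsum(y * y, axis=-1)
    sxy = np.cumsum(x * y, axis=-1)
    cov = sxy - sx * sy / n
    var_x = sxx - sx * sx / n
    var_y = syy - sy * sy / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_x * var_y)
    r = r[..., n_min - 1 :]
    if np.isnan(r).any():
        warnings.warn(
            "zero-variance prefix produced undefined correlations (NaN); "
            "these are excluded from aggregation",
            RuntimeWarning,
            stacklevel=2,
        )
    return r


def fisher_interval(
    r: np.ndarray | float, n: np.ndarray | int, level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z confidence interval for a sample correlation.

    Vectorized over ``r`` and ``n`` (broadcast together).  Requires
    ``n >= 4`` and ``|r| < 1``; bounds are strictly inside (-1, 1).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    r = np.asarray(r, dtype=float)
    n = np.asarray(n)
    if np.any(n < 4):
        raise ValueError("fisher_interval requires n >= 4")
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) >= 1):
        raise ValueError("fisher_interval requires |r| < 1")
    q = stats.norm.ppf(0.5 * (1.0 + level))
    z = np.arctanh(r)
    half = q / np.sqrt(n - 3.0)
    return np.tanh(z - half), np.tanh(z + half)


def estimate_trajectory_frequentist(
    stream: np.ndarray,
    n_min: int = 10,
    n_max: int | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> list[EstimateRecord]:
    """Per-prefix estimate records for a single trajectory.

    One record per ``n`` in ``n_min..n_max`` with the prefix correlation as
    point estimate and Fisher-z intervals at every requested level.
    """
    stream = np.asarray(stream, dtype=float)
    if n_max is None:
        n_max = stream.shape[0]
    r = prefix_pearson(stream[:n_max], n_min=n_min)
    ns = np.arange(n_min, n_max + 1)
    bounds = {lvl: fisher_interval(r, ns, lvl) for lvl in sorted(levels)}
    records = []
    for j, n in enumerate(ns):
        records.append(
            EstimateRecord(
                n=int(n),
                point=float(r[j]),
                intervals={
                    lvl: (float(lo[j]), float(hi[j]))
                    for lvl, (lo, hi) in bounds.items()
                },
                model_tag="frequentist",
            )
        )
    return records


def estimate_batch_frequentist(
    batch: TrajectoryBatch,
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_grid: Iterable[int] | None = None,
) -> BatchEstimates:
    """Vectorized frequentist estimates for a whole trajectory batch.

    ``n_grid`` restricts the evaluated sample sizes (default: every n in
    ``batch.n_min..batch.n_max``).
    """
    r_all = prefix_pearson(batch.data, n_min=batch.n_min)
    full_ns = np.arange(batch.n_min, batch.n_max + 1)
    if n_grid is None:
        ns = full_ns
        r = r_all
    else:
        ns = np.asarray(sorted(set(int(n) for n in n_grid)))
        if ns.min() < batch.n_min or ns.max() > batch.n_max:
            raise ValueError("n_grid outside batch bounds")
        r = r_all[:, ns - batch.n_min]
    intervals = {lvl: fisher_interval(r, ns, lvl) for lvl in sorted(levels)}
    return BatchEstimates(
        rho=batch.rho,
        n_grid=ns,
        point=r,
        intervals=intervals,
        model_tag="frequentist",
    )
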
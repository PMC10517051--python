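"""Shared result containers for per-prefix estimates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EstimateRecord", "BatchEstimates"]


@dataclass(frozen=True)
class EstimateRecord:
    """Point estimate and percentile intervals at one (replication, n).

    ``point`` is the sample correlation (frequentist) or the posterior mean
    of the correlation-scale slope (Bayesian).  ``intervals`` maps a level
    (e.g. 0.95) to its (lower, upper) bounds; levels are nested, so the 66%
    interval sits inside the 90% which sits inside the 95%.
    """

    n: int
    point: float
    intervals: dict[float, tuple[float, float]]
    model_tag: str

    def __post_init__(self) -> None:
        for level, (lo, hi) in self.intervals.items():
            if not 0 < level < 1:
                raise ValueError(f"interval level {level} outside (0, 1)")
            if not lo < hi:
                raise ValueError(f"degenerate interval at level {level}: ({lo}, {hi})")


@dataclass(frozen=True)
class BatchEstimates:
    """Array-of-records view over a whole batch of trajectories.

    ``point`` has shape (n_reps, len(n_grid)); each entry of ``intervals``
    maps a level to (lower, upper) arrays of the same shape.  Undefined
    estimates (zero-variance prefixes) are NaN and excluded downstream.
    """

    rho: float
    n_grid: np.ndarray
    point: np.ndarray = field(repr=False)
    intervals: dict[float, tuple[np.ndarray, np.ndarray]] = field(repr=False)
    model_tag: str = "frequentist"

    def __post_init__(self) -> None:
        r, k = self.point.shape
        if len(self.n_grid) != k:
            raise ValueError("n_grid length does not match point columns")
        for level, (lo, hi) in self.intervals.items():
            if lo.shape != (r, k) or hi.shape != (r, k):
                raise ValueError(f"interval arrays at level {level} have wrong shape")

    @property
    def n_reps(self) -> int:
        return self.point.shape[0]

    def record(self, replication: int, n: int) -> EstimateRecord:
        """Materialize one (replication, n) cell as an EstimateRecord."""
        j = int(np.flatnonzero(self.n_grid == n)[0])
        return EstimateRecord(
            n=int(n),
            point=float(self.point[replication, j]),
            intervals={
                lvl: (float(lo[replication, j]), float(hi[replication, j]))
                for lvl, (lo, hi) in self.intervals.items()
            },
            model_tag=self.model_tag,
        )
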
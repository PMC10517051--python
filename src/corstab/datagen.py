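"""Seeded bivariate-normal populations and sequential-sampling trajectories.

The simulation design mirrors a two-level seeding scheme: an *outer* seed,
a deterministic function of the population correlation rho, fixes the
population; an *inner* seed, a deterministic function of (rho, replication),
fixes the order in which observations are drawn from it.  One replication
produces one ordered stream of ``n_max`` (x, y) pairs whose length-``n``
prefix is "the sample at size n".

Two sampling modes are provided:

``finite_population``
    Draw one population of ``pop_size`` rows per rho and sample each
    trajectory from it sequentially without replacement.
``iid`` (default)
    Draw each trajectory's pairs directly from the bivariate normal.
    With ``n_max`` in the hundreds and a population of a million rows the
    two modes are statistically indistinguishable, and the i.i.d. stream
    avoids holding the population in memory.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PopulationSpec",
    "SeedLedger",
    "TrajectoryBatch",
    "generate_population",
    "sample_trajectory",
    "generate_batch",
    "export_prefix_json",
    "load_prefix_json",
]

DEFAULT_POP_SIZE = 1_000_000
DEFAULT_N_MIN = 10
DEFAULT_N_MAX = 500


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one bivariate-normal population.

    Parameters
    ----------
    rho
        Population correlation coefficient, strictly inside (-1, 1).
    pop_size
        Number of rows in the finite population (default one million).
    mean
        Population means of (x, y); default zeros.
    variances
        Population variances of (x, y); default ones.
    """

    rho: float
    pop_size: int = DEFAULT_POP_SIZE
    mean: tuple[float, float] = (0.0, 0.0)
    variances: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        if self.pop_size < 2:
            raise ValueError(f"pop_size must be >= 2, got {self.pop_size}")
        if len(self.mean) != 2:
            raise ValueError("mean must be a 2-vector")
        if len(self.variances) != 2 or min(self.variances) <= 0:
            raise ValueError("variances must be a positive 2-vector")


def _rho_key(rho: float) -> int:
    # stable non-negative integer identifying rho at 1e-6 resolution
    return int(round(rho * 1_000_000)) + 1_000_000


def outer_seed_for(master_seed: int, rho: float) -> int:
    """Deterministic outer seed (population seed) for a given rho."""
    ss = np.random.SeedSequence([int(master_seed), _rho_key(rho), 0])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def inner_seed_for(master_seed: int, rho: float, replication: int) -> int:
    """Deterministic inner seed for a given (rho, replication)."""
    ss = np.random.SeedSequence([int(master_seed), _rho_key(rho), 1, int(replication)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass(frozen=True)
class SeedLedger:
    """Record of every seed used by one trajectory batch.

    The ledger is sufficient to reproduce the batch bit-for-bit: the outer
    seed and each inner seed are pure functions of ``(master_seed, rho)``
    and ``(master_seed, rho, replication)`` respectively.
    """

    master_seed: int
    rho: float
    n_reps: int

    @property
    def outer(self) -> int:
        return outer_seed_for(self.master_seed, self.rho)

    def inner(self, replication: int) -> int:
        if not 0 <= replication < self.n_reps:
            raise IndexError(f"replication {replication} outside [0, {self.n_reps})")
        return inner_seed_for(self.master_seed, self.rho, replication)

    def inner_seeds(self) -> list[int]:
        return [self.inner(r) for r in range(self.n_reps)]

    def digest(self) -> str:
        """SHA-256 digest over the full seed roster (for manifests)."""
        h = hashlib.sha256()
        h.update(f"{self.master_seed}|{_rho_key(self.rho)}|{self.outer}".encode())
        for s in self.inner_seeds():
            h.update(s.to_bytes(8, "little"))
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "rho": self.rho,
            "n_reps": self.n_reps,
            "outer_seed": self.outer,
            "inner_seed_scheme": "SeedSequence([master, rho_key, 1, replication])",
            "digest": self.digest(),
        }


@dataclass(frozen=True)
class TrajectoryBatch:
    """A batch of sequential-sampling trajectories at one rho.

    ``data`` has shape ``(n_reps, n_max, 2)``; ``data[r, :n]`` is
    replication ``r``'s sample of size ``n`` (prefixes are nested by
    construction).
    """

    rho: float
    n_min: int
    n_max: int
    n_reps: int
    data: np.ndarray = field(repr=False)
    seed_ledger: SeedLedger
    mode: str = "iid"

    def __post_init__(self) -> None:
        if self.data.shape != (self.n_reps, self.n_max, 2):
            raise ValueError(
                f"data shape {self.data.shape} != {(self.n_reps, self.n_max, 2)}"
            )

    def prefix(self, replication: int, n: int) -> np.ndarray:
        """The first ``n`` (x, y) pairs of one replication."""
        if not self.n_min <= n <= self.n_max:
            raise ValueError(f"n={n} outside [{self.n_min}, {self.n_max}]")
        return self.data[replication, :n]

    def subset(self, n_reps: int) -> "TrajectoryBatch":
        """The first ``n_reps`` replications as a batch (shared seeds)."""
        if not 1 <= n_reps <= self.n_reps:
            raise ValueError(f"n_reps={n_reps} outside [1, {self.n_reps}]")
        return TrajectoryBatch(
            rho=self.rho,
            n_min=self.n_min,
            n_max=self.n_max,
            n_reps=n_reps,
            data=self.data[:n_reps],
            seed_ledger=SeedLedger(self.seed_ledger.master_seed, self.rho, n_reps),
            mode=self.mode,
        )


def _correlated_pairs(z: np.ndarray, spec: PopulationSpec) -> np.ndarray:
    """Map standard-normal draws ``z`` (…, 2) to the spec's bivariate normal."""
    rho = spec.rho
    out = np.empty_like(z)
    out[..., 0] = z[..., 0]
    out[..., 1] = rho * z[..., 0] + math.sqrt(1.0 - rho * rho) * z[..., 1]
    sd = np.sqrt(np.asarray(spec.variances))
    return out * sd + np.asarray(spec.mean)


def generate_population(spec: PopulationSpec, outer_seed: int) -> np.ndarray:
    """Generate the population matrix of ``pop_size`` (x, y) pairs.

    Deterministic in ``(spec, outer_seed)``; the empirical correlation of
    the returned matrix is within O(1/sqrt(pop_size)) of ``spec.rho``.
    """
    rng = np.random.default_rng(int(outer_seed))
    z = rng.standard_normal((spec.pop_size, 2))
    return _correlated_pairs(z, spec)


def _draw_without_replacement(
    rng: np.random.Generator, pop_size: int, k: int
) -> np.ndarray:
    """Ordered sample of ``k`` distinct indices from ``range(pop_size)``.

    Sequential draws with duplicates skipped, which is distributionally the
    sequential without-replacement scheme while staying O(k) for
    ``k << pop_size``.
    """
    if k > pop_size:
        raise ValueError(f"cannot draw {k} distinct rows from {pop_size}")
    chosen: list[int] = []
    seen: set[int] = set()
    while len(chosen) < k:
        need = k - len(chosen)
        # small oversample to absorb collisions
        batch = rng.integers(0, pop_size, size=need + 8 + need // 8)
        for idx in batch:
            i = int(idx)
            if i not in seen:
                seen.add(i)
                chosen.append(i)
                if len(chosen) == k:
                    break
    return np.asarray(chosen, dtype=np.int64)


def sample_trajectory(
    population: np.ndarray,
    inner_seed: int,
    n_min: int = DEFAULT_N_MIN,
    n_max: int = DEFAULT_N_MAX,
) -> np.ndarray:
    """One ordered stream of ``n_max`` pairs drawn without replacement.

    The first ``n_min`` rows are a simple random sample; each subsequent row
    is drawn from the remainder, so every length-``n`` prefix is the sample
    at size ``n`` and prefixes are nested.
    """
    if n_min < 2:
        raise ValueError(f"n_min must be >= 2, got {n_min}")
    if n_max < n_min:
        raise ValueError(f"n_max={n_max} < n_min={n_min}")
    if n_max > len(population):
        raise ValueError(f"n_max={n_max} exceeds population size {len(population)}")
    rng = np.random.default_rng(int(inner_seed))
    idx = _draw_without_replacement(rng, len(population), n_max)
    return population[idx]


def _iid_trajectory(
    spec: PopulationSpec, inner_seed: int, n_max: int
) -> np.ndarray:
    rng = np.random.default_rng(int(inner_seed))
    z = rng.standard_normal((n_max, 2))
    return _correlated_pairs(z, spec)


def generate_batch(
    spec: PopulationSpec,
    n_reps: int,
    n_min: int = DEFAULT_N_MIN,
    n_max: int = DEFAULT_N_MAX,
    mode: Literal["finite_population", "iid"] = "iid",
    master_seed: int = 0,
) -> TrajectoryBatch:
    """Generate ``n_reps`` trajectories at one rho.

    In ``finite_population`` mode all replications share one population
    (outer seed fixed by rho) and differ only by inner seed; in ``iid``
    mode pairs are drawn directly from the bivariate normal, one generator
    per replication, with the same inner-seed roster.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if mode not in ("finite_population", "iid"):
        raise ValueError(f"unknown mode {mode!r}")
    ledger = SeedLedger(int(master_seed), spec.rho, n_reps)
    data = np.empty((n_reps, n_max, 2))
    if mode == "finite_population":
        population = generate_population(spec, ledger.outer)
        for r in range(n_reps):
            data[r] = sample_trajectory(population, ledger.inner(r), n_min, n_max)
    else:
        for r in range(n_reps):
            data[r] = _iid_trajectory(spec, ledger.inner(r), n_max)
    return TrajectoryBatch(
        rho=spec.rho,
        n_min=n_min,
        n_max=n_max,
        n_reps=n_reps,
        data=data,
        seed_ledger=ledger,
        mode=mode,
    )


def export_prefix_json(batch: TrajectoryBatch, replication: int, n: int, path) -> None:
    """Write one prefix as ``{"N": n, "x": [...], "y": [...]}`` (debug aid)."""
    pre = batch.prefix(replication, n)
    obj = {"N": int(n), "x": pre[:, 0].tolist(), "y": pre[:, 1].tolist()}
    Path(path).write_text(json.dumps(obj))


def load_prefix_json(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a prefix export back as ``(x, y)`` arrays."""
    obj = json.loads(Path(path).read_text())
    x = np.asarray(obj["x"], dtype=float)
    y = np.asarray(obj["y"], dtype=float)
    if len(x) != obj["N"] or len(y) != obj["N"]:
        raise ValueError("prefix file is inconsistent: N does not match arrays")
    return x, y
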
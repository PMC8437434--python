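"""Lightweight containers for kinetic traces and their experimental conditions.

Everything downstream (preprocessing, global fitting, synthetic generation)
moves data around in these containers. They are deliberately thin wrappers
over numpy arrays plus condition metadata; tabular round-trips go through
pandas in :mod:`taukinetics.traces`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["Condition", "RawTrace", "MassTrace", "KineticDataset"]


@dataclass(frozen=True)
class Condition:
    """Experimental condition of a single well.

    Parameters
    ----------
    m0 : float
        Initial monomer concentration, µM.
    chaperone : str or None
        Chaperone identity (``None`` / ``"none"`` for tau alone).
    chaperone_conc : float
        Chaperone concentration, µM.
    seeded : bool
        Whether preformed seeds were added.
    seed_mass : float
        Seed mass concentration M0, µM (0 for unseeded wells).
    replicate : int
        Replicate identifier.
    """

    m0: float
    chaperone: str | None = None
    chaperone_conc: float = 0.0
    seeded: bool = False
    seed_mass: float = 0.0
    replicate: int = 0

    def __post_init__(self):
        if not np.isfinite(self.m0) or self.m0 <= 0:
            raise InvalidInputError(f"m0 must be positive and finite, got {self.m0}")
        if self.seed_mass < 0 or self.chaperone_conc < 0:
            raise InvalidInputError("concentrations must be non-negative")
        if self.seeded and self.seed_mass <= 0:
            raise InvalidInputError("seeded condition requires seed_mass > 0")

    @property
    def total_mass(self) -> float:
        """Total tau mass m0 + M0, µM (conserved along a trajectory)."""
        return self.m0 + self.seed_mass

    def key(self) -> tuple:
        """Hashable condition key ignoring the replicate id."""
        return (self.m0, self.chaperone or "none", self.chaperone_conc,
                self.seeded, self.seed_mass)


def _check_series(times, values, min_len=2):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise InvalidInputError("times and values must be equal-length 1-D arrays")
    if times.size < min_len:
        raise InvalidInputError(f"need at least {min_len} points, got {times.size}")
    if not np.all(np.isfinite(values)) or not np.all(np.isfinite(times)):
        raise InvalidInputError("non-finite entries in trace")
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    return times, values


@dataclass(frozen=True)
class RawTrace:
    """A ThT fluorescence time course in arbitrary units."""

    times: np.ndarray  # min
    signal: np.ndarray  # a.u.
    condition: Condition

    def __post_init__(self):
        t, s = _check_series(self.times, self.signal)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)

    @property
    def values(self) -> np.ndarray:
        return self.signal

    def with_signal(self, signal) -> "RawTrace":
        return RawTrace(self.times.copy(), np.asarray(signal, float), self.condition)


@dataclass(frozen=True)
class MassTrace:
    """A fibril mass-concentration time course, µM.

    The invariant 0 ≤ M ≤ 1.05·(m0 + seed_mass) allows 5% headroom for
    measurement noise; traces breaching it are constructible but flagged
    through :attr:`amplitude_flagged`.
    """

    times: np.ndarray  # min
    M: np.ndarray  # µM
    condition: Condition

    def __post_init__(self):
        t, m = _check_series(self.times, self.M)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "M", m)

    @property
    def values(self) -> np.ndarray:
        return self.M

    @property
    def amplitude_flagged(self) -> bool:
        """True when the trace exceeds the physical amplitude bound."""
        cap = 1.05 * self.condition.total_mass
        return bool(np.any(self.M > cap) or np.any(self.M < -0.05 * cap))

    def with_values(self, M) -> "MassTrace":
        return MassTrace(self.times.copy(), np.asarray(M, float), self.condition)


@dataclass
class KineticDataset:
    """A collection of mass traces grouped by condition.

    ``replicate_sets`` optionally partitions traces into independent sets for
    rate-uncertainty estimation (labels parallel to ``traces``).
    """

    traces: list[MassTrace] = field(default_factory=list)
    replicate_sets: list[int] | None = None

    def __post_init__(self):
        if self.replicate_sets is not None and len(self.replicate_sets) != len(self.traces):
            raise InvalidInputError("replicate_sets must parallel traces")

    def __iter__(self) -> Iterator[MassTrace]:
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def unseeded(self) -> "KineticDataset":
        return self.filter(lambda c: not c.seeded)

    @property
    def seeded(self) -> "KineticDataset":
        return self.filter(lambda c: c.seeded)

    def filter(self, predicate) -> "KineticDataset":
        keep = [i for i, tr in enumerate(self.traces) if predicate(tr.condition)]
        sets = None
        if self.replicate_sets is not None:
            sets = [self.replicate_sets[i] for i in keep]
        return KineticDataset([self.traces[i] for i in keep], sets)

    def monomer_concentrations(self) -> np.ndarray:
        return np.unique([tr.condition.m0 for tr in self.traces])

    def chaperone_concentrations(self) -> np.ndarray:
        return np.unique([tr.condition.chaperone_conc for tr in self.traces])

    def group_by_condition(self) -> dict[tuple, list[MassTrace]]:
        groups: dict[tuple, list[MassTrace]] = {}
        for tr in self.traces:
            groups.setdefault(tr.condition.key(), []).append(tr)
        return groups

    def split_replicate_sets(self) -> list["KineticDataset"]:
        if self.replicate_sets is None:
            raise InvalidInputError("dataset carries no replicate-set labels")
        labels = sorted(set(self.replicate_sets))
        out = []
        for lab in labels:
            idx = [i for i, l in enumerate(self.replicate_sets) if l == lab]
            out.append(KineticDataset([self.traces[i] for i in idx]))
        return out

    def extend(self, other: Iterable[MassTrace]) -> None:
        for tr in other:
            self.traces.append(tr)
        if self.replicate_sets is not None:
            raise InvalidInputError("cannot extend a dataset with replicate-set labels")
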
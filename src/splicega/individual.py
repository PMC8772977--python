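"""Binary-inclusion individuals over a feature index set."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ConfigError


@dataclass
class Individual:
    """A candidate feature subset encoded as a 0/1 vector of length q.

    Bit ``i`` selects feature column ``i``; the set bits form the active
    set A, the clear bits the inactive set I, which always partition
    ``{0, ..., q-1}``.
    """

    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1:
            raise ConfigError("bits must be a 1-d vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise ConfigError("bits must be 0/1")

    @classmethod
    def from_support(cls, support, q: int) -> "Individual":
        bits = np.zeros(q, dtype=np.int8)
        bits[np.asarray(sorted(support), dtype=int)] = 1
        return cls(bits)

    @property
    def q(self) -> int:
        return self.bits.size

    @property
    def active(self) -> np.ndarray:
        """Indices of selected features (the active set A)."""
        return np.flatnonzero(self.bits == 1)

    @property
    def inactive(self) -> np.ndarray:
        """Indices of excluded features (the inactive set I)."""
        return np.flatnonzero(self.bits == 0)

    @property
    def size(self) -> int:
        return int(self.bits.sum())

    def key(self) -> bytes:
        """Hashable key for fitness caching."""
        return self.bits.tobytes()

    def copy(self) -> "Individual":
        return Individual(self.bits.copy(), self.fitness)
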
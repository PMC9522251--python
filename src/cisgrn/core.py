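"""Shared coordinate model: genome, intervals, gene models, signal tracks.

All internal coordinates are 0-based half-open.  GTF import/export (see
:mod:`cisgrn.io`) is the only place 1-based inclusive coordinates appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


class CoordinateError(ValueError):
    """Raised when genomic coordinates violate an invariant."""


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length (bp) lookup.

    Stands in for a genome index; only sizes are modelled.
    """

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise CoordinateError(f"chromosome {chrom!r} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __len__(self) -> int:
        return len(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start {self.start} for {self.name or self.chrom}")
        if self.start >= self.end:
            raise CoordinateError(
                f"start {self.start} >= end {self.end} for {self.name or self.chrom}"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Single-bp region center: floor of the interval midpoint."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def validate_against(self, genome: Genome) -> None:
        if self.chrom not in genome:
            raise CoordinateError(f"unknown chromosome {self.chrom!r}")
        size = genome.chrom_sizes[self.chrom]
        if self.end > size:
            raise CoordinateError(
                f"interval end {self.end} exceeds {self.chrom} length {size}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Gene-level skeleton: one stranded interval per gene id.

    Strand must be '+' or '-' because the TSS is undefined otherwise.
    """

    gene_id: str
    interval: GenomicInterval
    is_tf: bool = False
    tf_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise CoordinateError(
                f"gene {self.gene_id} has strand {self.interval.strand!r}; "
                "genes must be stranded"
            )


class SignalTrack:
    """Piecewise-constant signal over a genome.

    Stored per chromosome as sorted, non-overlapping ``(start, end, value)``
    steps.  Queries at uncovered positions return 0.0, matching the sparse
    bedGraph convention.
    """

    def __init__(self, steps: Optional[Iterable[Tuple[str, int, int, float]]] = None) -> None:
        self._raw: Dict[str, list] = {}
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if steps is not None:
            for chrom, start, end, value in steps:
                self.add_step(chrom, start, end, value)
            self.freeze()

    @classmethod
    def from_arrays(
        cls,
        per_chrom: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> "SignalTrack":
        """Bulk constructor from per-chromosome (starts, ends, values) arrays.

        Arrays must already be sorted by start; overlap and validity checks
        still apply.
        """
        track = cls()
        for chrom, (starts, ends, values) in per_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if np.any(starts < 0) or np.any(starts >= ends):
                raise CoordinateError(f"invalid steps on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite signal values on {chrom}")
            if np.any(np.diff(starts) < 0):
                order = np.argsort(starts, kind="stable")
                starts, ends, values = starts[order], ends[order], values[order]
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise CoordinateError(f"overlapping steps on {chrom}")
            track._raw[chrom] = list(zip(starts.tolist(), ends.tolist(),
                                         values.tolist()))
            track._index[chrom] = (starts, ends, values)
        return track

    def add_step(self, chrom: str, start: int, end: int, value: float) -> None:
        if start < 0 or start >= end:
            raise CoordinateError(f"bad step [{start},{end}) on {chrom}")
        if not np.isfinite(value):
            raise ValueError(f"non-finite signal value {value!r} on {chrom}")
        self._raw.setdefault(chrom, []).append((start, end, float(value)))
        self._index.pop(chrom, None)

    def freeze(self) -> "SignalTrack":
        """Sort and index all steps; rejects overlapping steps."""
        for chrom in self._raw:
            self._build(chrom)
        return self

    def _build(self, chrom: str) -> None:
        rows = sorted(self._raw.get(chrom, ()))
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=np.float64)
        if len(rows) > 1 and np.any(starts[1:] < ends[:-1]):
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise CoordinateError(
                f"overlapping steps on {chrom}: [{starts[i]},{ends[i]}) and "
                f"[{starts[i + 1]},{ends[i + 1]})"
            )
        self._index[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self._raw))

    def steps(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._index:
            self._build(chrom)
        return self._index[chrom]

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised point query; off-track positions (incl. negative) give 0."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._raw:
            return np.zeros(positions.shape, dtype=np.float64)
        starts, ends, values = self.steps(chrom)
        idx = np.searchsorted(starts, positions, side="right") - 1
        out = np.zeros(positions.shape, dtype=np.float64)
        valid = idx >= 0
        safe = np.where(valid, idx, 0)
        covered = valid & (positions < ends[safe])
        out[covered] = values[safe[covered]]
        return out

    def query(self, chrom: str, position: int) -> float:
        """Signal value at a single position (0 where no step covers it)."""
        return float(self.values_at(chrom, np.array([position]))[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        for chrom in self.chroms:
            for a, b in zip(self.steps(chrom), other.steps(chrom)):
                if not np.array_equal(a, b):
                    return False
        return True
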
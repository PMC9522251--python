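"""PWM information measures and the motif -> TF mapping.

One motif can serve several TFs (paralogous families share near-identical
matrices), so footprint calls are expanded once per mapped TF before any
per-TF counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from cisgrn.grn import FootprintCall

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class Motif:
    """A position weight matrix of column probability vectors over ACGT.

    ``pwm`` has shape (4, n_columns), rows in A, C, G, T order; every
    column must sum to 1.
    """

    motif_id: str
    pwm: np.ndarray

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=np.float64)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[0] != 4 or pwm.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: PWM must be 4 x n (n >= 1)")
        if np.any(pwm < 0) or np.any(pwm > 1):
            raise ValueError(f"motif {self.motif_id}: probabilities outside [0,1]")
        if np.any(np.abs(pwm.sum(axis=0) - 1.0) > 1e-6):
            raise ValueError(f"motif {self.motif_id}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    @property
    def mean_entropy(self) -> float:
        return motif_information(self)[0]

    @property
    def total_ic(self) -> float:
        return motif_information(self)[1]


def column_entropy(column: Sequence[float]) -> float:
    """Shannon entropy of one PWM column in bits, with 0*log(0) = 0."""
    col = np.asarray(column, dtype=np.float64)
    if abs(col.sum() - 1.0) > 1e-6:
        raise ValueError(f"column sums to {col.sum()}, not 1")
    nz = col[col > 0]
    return float(-(nz * np.log2(nz)).sum())


def motif_information(m: Motif) -> Tuple[float, float]:
    """(mean column entropy, total information content), both in bits.

    Total IC is the sum over columns of (2 - H); it satisfies
    ``total_ic == n_columns * (2 - mean_entropy)`` exactly.  Both scalars
    are reported because either can serve as the motif's summary.
    """
    entropies = [column_entropy(m.pwm[:, j]) for j in range(m.length)]
    mean_h = float(np.mean(entropies))
    total_ic = float(sum(2.0 - h for h in entropies))
    return mean_h, total_ic


class MotifTFMap:
    """Many-to-many motif_id <-> tf_gene_id mapping with unique pairs."""

    def __init__(self) -> None:
        self._by_motif: Dict[str, List[str]] = {}
        self._pairs: set = set()

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "MotifTFMap":
        m = cls()
        for motif_id, tf in pairs:
            m.add(str(motif_id), str(tf))
        return m

    def add(self, motif_id: str, tf_gene_id: str) -> None:
        if (motif_id, tf_gene_id) in self._pairs:
            return
        self._pairs.add((motif_id, tf_gene_id))
        self._by_motif.setdefault(motif_id, []).append(tf_gene_id)

    def tfs_for(self, motif_id: str) -> List[str]:
        return list(self._by_motif.get(motif_id, ()))

    def pairs(self) -> List[Tuple[str, str]]:
        return sorted(self._pairs)

    @property
    def motif_ids(self) -> List[str]:
        return sorted(self._by_motif)

    @property
    def tf_ids(self) -> List[str]:
        return sorted({tf for _, tf in self._pairs})

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self._by_motif


def expand_motif_hits(
    footprints: Sequence["FootprintCall"], mapping: MotifTFMap
) -> List[Tuple[str, "FootprintCall"]]:
    """Emit each footprint once per TF mapped to its motif.

    Footprints whose motif has no mapped TF are dropped; the dropped count
    is logged.
    """
    if len(mapping) == 0:
        raise ValueError("motif->TF map is empty")
    out: List[Tuple[str, "FootprintCall"]] = []
    dropped = 0
    for fp in footprints:
        tfs = mapping.tfs_for(fp.motif_id)
        if not tfs:
            dropped += 1
            continue
        out.extend((tf, fp) for tf in tfs)
    if dropped:
        logger.warning("expand_motif_hits: dropped %d footprints with unmapped motifs",
                       dropped)
    return out
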
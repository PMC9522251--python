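"""Enhancer-like region calling from histone-mark peak proximity.

An H3K27ac peak is called an enhancer-like region when the edge-to-edge gap
to the nearest H3K4me1 peak on the same chromosome is at most ``max_gap``
(500 bp by default).  Signal at regions is summarised as the mean of a
track sampled every 10 bp across +/-1000 bp around the region center, and
compared against random genomic background with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from cisgrn.core import Genome, GenomicInterval, SignalTrack
from cisgrn.expression import wilcoxon_rank_sum

MARKS = ("H3K27ac", "H3K4me1")

#: Sampling grid for mean peak value: +/-1000 bp around the center, 10 bp apart.
MPV_HALF_SPAN = 1000
MPV_STEP = 10
_MPV_OFFSETS = np.arange(-MPV_HALF_SPAN, MPV_HALF_SPAN + 1, MPV_STEP)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    mark: str
    peak_id: str

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}")


@dataclass(frozen=True)
class EnhancerRegion:
    """An H3K27ac peak qualifying via a nearby H3K4me1 partner.

    The enhancer interval is the H3K27ac peak itself, not the union with
    the partner.
    """

    interval: GenomicInterval
    partner_me1_id: str
    gap_bp: int

    @property
    def enhancer_id(self) -> str:
        return self.interval.name


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap in bp; 0 for overlapping or book-ended intervals."""
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    return max(0, b.start - a.end, a.start - b.end)


def call_enhancers(
    ac: Sequence[Peak], me1: Sequence[Peak], max_gap: int = 500
) -> List[EnhancerRegion]:
    """Select H3K27ac peaks with an H3K4me1 peak within ``max_gap`` bp.

    The partner is the gap-minimising H3K4me1 peak (ties broken by leftmost
    start, then end, then peak_id).  Output is in genomic order and is
    invariant to input ordering.
    """
    me1_by_chrom: Dict[str, list] = defaultdict(list)
    for p in me1:
        me1_by_chrom[p.interval.chrom].append(p)
    ac_by_chrom: Dict[str, list] = defaultdict(list)
    for p in ac:
        ac_by_chrom[p.interval.chrom].append(p)

    out: List[EnhancerRegion] = []
    for chrom, ac_peaks in ac_by_chrom.items():
        partners = me1_by_chrom.get(chrom)
        if not partners:
            continue
        # Sort partners so that np.argmin's first-minimum rule implements the
        # (gap, start, end, peak_id) tie-break.
        partners = sorted(
            partners, key=lambda p: (p.interval.start, p.interval.end, p.peak_id)
        )
        a_start = np.array([p.interval.start for p in ac_peaks])[:, None]
        a_end = np.array([p.interval.end for p in ac_peaks])[:, None]
        m_start = np.array([p.interval.start for p in partners])[None, :]
        m_end = np.array([p.interval.end for p in partners])[None, :]
        gaps = np.maximum(0, np.maximum(m_start - a_end, a_start - m_end))
        best = np.argmin(gaps, axis=1)
        best_gap = gaps[np.arange(len(ac_peaks)), best]
        for i, peak in enumerate(ac_peaks):
            if best_gap[i] <= max_gap:
                out.append(EnhancerRegion(
                    interval=peak.interval,
                    partner_me1_id=partners[best[i]].peak_id,
                    gap_bp=int(best_gap[i]),
                ))
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end,
                            e.interval.name))
    return out


def mean_peak_values(
    track: SignalTrack, chroms: Sequence[str], centers: Sequence[int]
) -> np.ndarray:
    """Vectorised mean peak value at many (chrom, center) pairs.

    For each center, the mean of the 201 track values at center-1000,
    center-990, ..., center+1000; positions off the track contribute 0.
    """
    chroms = np.asarray(chroms, dtype=object)
    centers = np.asarray(centers, dtype=np.int64)
    out = np.empty(len(centers), dtype=np.float64)
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        grid = centers[sel][:, None] + _MPV_OFFSETS[None, :]
        vals = track.values_at(str(chrom), grid.ravel()).reshape(grid.shape)
        out[sel] = vals.mean(axis=1)
    return out


def mean_peak_value(track: SignalTrack, chrom: str, center: int) -> float:
    """Mean track value on the 10 bp grid spanning +/-1000 bp of ``center``."""
    if center < 0:
        raise ValueError(f"negative center {center}")
    return float(mean_peak_values(track, [chrom], [center])[0])


def random_regions(
    genome: Genome, n: int, length: int, seed: int
) -> List[GenomicInterval]:
    """Fixed-length random regions, chromosome drawn proportional to length.

    Start positions are uniform in ``[0, chrom_len - length]``; the output
    is deterministic given the seed.
    """
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.float64)
    if any(s < length for s in sizes):
        raise ValueError(f"region length {length} exceeds a chromosome length")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    out = []
    for i, ci in enumerate(which):
        start = int(rng.integers(0, genome.chrom_sizes[chroms[ci]] - length + 1))
        out.append(GenomicInterval(chroms[ci], start, start + length, name=f"rand{i}"))
    return out


def region_signal_test(
    track: SignalTrack,
    regions_a: Sequence[GenomicInterval],
    regions_b: Sequence[GenomicInterval],
) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Mean peak values at two region sets plus a two-sided rank-sum test.

    Returns ``(values_a, values_b, statistic, p)`` where values are the
    per-region mean peak values at each region's center.
    """
    if not len(regions_a) or not len(regions_b):
        raise ValueError("both region lists must be non-empty")
    va = mean_peak_values(track, [r.chrom for r in regions_a],
                          [r.center for r in regions_a])
    vb = mean_peak_values(track, [r.chrom for r in regions_b],
                          [r.center for r in regions_b])
    stat, p = wilcoxon_rank_sum(va, vb)
    return va, vb, stat, p
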
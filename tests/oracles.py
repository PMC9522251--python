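"""Independent brute-force reference implementations used as test oracles.

These deliberately use plain Python loops over all pairs, sharing no code
with the package's indexed/vectorised implementations.
"""

from cisgrn.enhancers import EnhancerRegion
from cisgrn.grn import EnhancerTargetAssignment


def brute_force_enhancers(ac_peaks, me1_peaks, max_gap=500):
    """All-pairs minimal-gap enhancer selection."""
    out = []
    for peak in ac_peaks:
        best = None
        for cand in me1_peaks:
            if cand.interval.chrom != peak.interval.chrom:
                continue
            gap = max(
                0,
                cand.interval.start - peak.interval.end,
                peak.interval.start - cand.interval.end,
            )
            key = (gap, cand.interval.start, cand.interval.end, cand.peak_id)
            if best is None or key < best:
                best = key
                best_peak = cand
        if best is not None and best[0] <= max_gap:
            out.append(EnhancerRegion(
                interval=peak.interval,
                partner_me1_id=best_peak.peak_id,
                gap_bp=best[0],
            ))
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start,
                            e.interval.end, e.interval.name))
    return out


def brute_force_assign(enhancers, genes):
    """Exhaustive min-over-genes nearest-TSS assignment."""
    out = []
    for enh in enhancers:
        best = None
        for g in genes:
            if g.interval.chrom != enh.interval.chrom:
                continue
            tss = g.interval.start if g.interval.strand == "+" else g.interval.end - 1
            if enh.interval.start <= tss < enh.interval.end:
                d = 0
            else:
                d = min(abs(tss - enh.interval.start),
                        abs(tss - (enh.interval.end - 1)))
            key = (d, tss, g.gene_id)
            if best is None or key < best:
                best = key
                best_gene = g
        if best is not None:
            out.append(EnhancerTargetAssignment(
                enhancer_id=enh.enhancer_id,
                gene_id=best_gene.gene_id,
                distance=best[0],
            ))
    return out


def random_peak_set(rng, n, mark, prefix, n_chroms=3, chrom_length=100_000):
    """Random possibly-overlapping peaks for oracle-equivalence tests."""
    from cisgrn.core import GenomicInterval
    from cisgrn.enhancers import Peak

    peaks = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_length - 600))
        width = int(rng.integers(20, 600))
        peaks.append(Peak(
            GenomicInterval(chrom, start, start + width, name=f"{prefix}{i}"),
            mark, f"{prefix}{i}",
        ))
    return peaks
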
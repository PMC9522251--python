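"""Enhancer -> target assignment and regulatory network assembly.

Enhancers are assigned to the gene with the nearest TSS; footprints that
overlap an enhancer by at least 1 bp create TF -> target links, expanded
once per TF mapped to the footprint's motif.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from cisgrn.core import GeneModel, GenomicInterval
from cisgrn.enhancers import EnhancerRegion
from cisgrn.expression import ProportionProfile
from cisgrn.motifs import MotifTFMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FootprintCall:
    """A motif occurrence with a footprint score and bound/unbound flag."""

    interval: GenomicInterval
    motif_id: str
    score: float
    bound: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite footprint score for {self.motif_id}")


@dataclass(frozen=True)
class EnhancerTargetAssignment:
    enhancer_id: str
    gene_id: str
    distance: int  # bp; 0 when the TSS lies inside the enhancer


@dataclass(frozen=True)
class RegulatoryLink:
    """TF -> target edge evidenced by one footprint inside one enhancer."""

    tf_gene_id: str
    target_gene_id: str
    enhancer_id: str
    bound: bool
    motif_id: str


def tss_of(g: GeneModel) -> int:
    """TSS position: interval start on '+', ``end - 1`` on '-'."""
    if g.interval.strand == "+":
        return g.interval.start
    if g.interval.strand == "-":
        return g.interval.end - 1
    raise ValueError(f"gene {g.gene_id} is strandless; TSS undefined")


def _enhancer_tss_distance(start: int, end: int, tss: int) -> int:
    if start <= tss < end:
        return 0
    return min(abs(tss - start), abs(tss - (end - 1)))


def assign_targets(
    enhancers: Sequence[EnhancerRegion],
    genes: Sequence[GeneModel],
    *,
    min_expression: Optional[Mapping[str, float]] = None,
    expression_floor: float = 0.0,
) -> List[EnhancerTargetAssignment]:
    """Assign every enhancer to the gene with the nearest TSS.

    Distance is 0 when the TSS falls inside the enhancer, else the distance
    from the TSS to the nearer enhancer edge.  Ties break to the gene whose
    TSS has the smaller coordinate, then to the lexicographically smaller
    gene_id.  Enhancers on chromosomes without genes are skipped with a
    warning.

    When ``min_expression`` is given (gene_id -> expression level, e.g.
    X1+X2 TPM), genes below ``expression_floor`` are skipped before taking
    the nearest — the optional expression-aware assignment rule.
    """
    by_chrom: Dict[str, list] = defaultdict(list)
    for g in genes:
        if min_expression is not None and min_expression.get(g.gene_id, 0.0) < expression_floor:
            continue
        by_chrom[g.interval.chrom].append(g)

    index: Dict[str, Tuple[np.ndarray, list]] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (tss_of(g), g.gene_id))
        index[chrom] = (np.array([tss_of(g) for g in glist]), glist)

    out: List[EnhancerTargetAssignment] = []
    skipped = 0
    for enh in enhancers:
        chrom = enh.interval.chrom
        if chrom not in index or not index[chrom][1]:
            skipped += 1
            continue
        tss, glist = index[chrom]
        start, end = enh.interval.start, enh.interval.end
        dist = np.minimum(np.abs(tss - start), np.abs(tss - (end - 1)))
        dist = np.where((tss >= start) & (tss < end), 0, dist)
        # argmin on TSS-sorted genes gives the smallest-TSS minimiser; equal
        # TSS positions were pre-sorted by gene_id.
        best = int(np.argmin(dist))
        out.append(EnhancerTargetAssignment(
            enhancer_id=enh.enhancer_id,
            gene_id=glist[best].gene_id,
            distance=int(dist[best]),
        ))
    if skipped:
        logger.warning("assign_targets: skipped %d enhancers on gene-less chromosomes",
                       skipped)
    return out


def build_links(
    enhancers: Sequence[EnhancerRegion],
    assignments: Sequence[EnhancerTargetAssignment],
    footprints: Sequence[FootprintCall],
    mapping: MotifTFMap,
    tf_genes: Set[str],
) -> List[RegulatoryLink]:
    """Create TF -> target links from footprints overlapping enhancers.

    A footprint overlapping an assigned enhancer (>= 1 bp) yields one link
    per TF mapped to its motif (restricted to ``tf_genes``), carrying the
    footprint's bound flag.  Footprints outside all enhancers yield nothing.
    Links are deduplicated on (tf, target, enhancer, motif, bound).
    """
    target_of = {a.enhancer_id: a.gene_id for a in assignments}
    enh_by_chrom: Dict[str, list] = defaultdict(list)
    for e in enhancers:
        if e.enhancer_id in target_of:
            enh_by_chrom[e.interval.chrom].append(e)
    index: Dict[str, Tuple[np.ndarray, np.ndarray, list]] = {}
    for chrom, elist in enh_by_chrom.items():
        elist.sort(key=lambda e: (e.interval.start, e.interval.end))
        index[chrom] = (
            np.array([e.interval.start for e in elist]),
            np.array([e.interval.end for e in elist]),
            elist,
        )

    seen = set()
    out: List[RegulatoryLink] = []
    for fp in footprints:
        chrom = fp.interval.chrom
        if chrom not in index:
            continue
        starts, ends, elist = index[chrom]
        # overlap: enh.start < fp.end and fp.start < enh.end
        hi = int(np.searchsorted(starts, fp.interval.end, side="left"))
        for e in elist[:hi]:
            if e.interval.end <= fp.interval.start:
                continue
            target = target_of[e.enhancer_id]
            for tf in mapping.tfs_for(fp.motif_id):
                if tf not in tf_genes:
                    continue
                key = (tf, target, e.enhancer_id, fp.motif_id, fp.bound)
                if key in seen:
                    continue
                seen.add(key)
                out.append(RegulatoryLink(
                    tf_gene_id=tf,
                    target_gene_id=target,
                    enhancer_id=e.enhancer_id,
                    bound=fp.bound,
                    motif_id=fp.motif_id,
                ))
    return out


def count_bound_motifs(
    footprints: Sequence[FootprintCall], mapping: MotifTFMap
) -> Dict[str, int]:
    """Genome-wide bound-footprint count per TF (0 for TFs with no hits)."""
    counts: Dict[str, int] = {tf: 0 for tf in mapping.tf_ids}
    for fp in footprints:
        if not fp.bound:
            continue
        for tf in mapping.tfs_for(fp.motif_id):
            counts[tf] += 1
    return counts


def subnetwork_x1(
    links: Sequence[RegulatoryLink],
    profiles: Mapping[str, ProportionProfile],
    tpm_x1: Mapping[str, float],
    threshold: float = 1.0 / 3.0,
) -> nx.DiGraph:
    """GRN restricted to TFs with X1 proportional expression above ``threshold``.

    Nodes carry ``tpm_x1`` and ``p1`` attributes; edges are deduplicated
    bound links between retained nodes, with a ``support`` count of the
    distinct supporting (enhancer, motif) pairs.
    """
    retained = {
        gene for gene, prof in profiles.items() if prof.p1 > threshold
    }
    g = nx.DiGraph()
    support: Dict[Tuple[str, str], set] = defaultdict(set)
    for link in links:
        if not link.bound:
            continue
        if link.tf_gene_id in retained and link.target_gene_id in retained:
            support[(link.tf_gene_id, link.target_gene_id)].add(
                (link.enhancer_id, link.motif_id)
            )
    for (tf, target), evid in support.items():
        for gene in (tf, target):
            if gene not in g:
                g.add_node(gene,
                           tpm_x1=float(tpm_x1.get(gene, 0.0)),
                           p1=profiles[gene].p1)
        g.add_edge(tf, target, bound=True, support=len(evid))
    return g


def links_table_rows(
    links: Sequence[RegulatoryLink],
    assignments: Sequence[EnhancerTargetAssignment],
) -> List[dict]:
    """Rows for the links TSV export (tf, target, enhancer, motif, bound, distance)."""
    dist = {a.enhancer_id: a.distance for a in assignments}
    return [
        {
            "tf_gene_id": l.tf_gene_id,
            "target_gene_id": l.target_gene_id,
            "enhancer_id": l.enhancer_id,
            "motif_id": l.motif_id,
            "bound": int(l.bound),
            "distance": dist.get(l.enhancer_id, -1),
        }
        for l in links
    ]
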
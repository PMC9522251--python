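"""Synthetic pipeline inputs with known ground truth.

Emits every file the pipeline consumes — genome sizes, gene models, peak
sets, signal tracks, footprint calls, motifs, expression tables, and
knockdown DE lists — from one master seed, together with the ground truth
(planted enhancers, TF->target adjacency, per-gene compartment class,
per-knockdown true DE sets) needed for truth-aware tests.

Planted structure mirrors the statistical shape of real data: co-located
H3K27ac/H3K4me1 peak pairs (gap <= max_gap) at enhancers, bimodal H3K4me1
flanking a central H3K27ac bump, elevated ATAC/footprint-score signal and
a depressed H3K4me1 log2FC knockdown track at enhancers, Dirichlet
compartment proportions per enrichment class, and DE sets enriched for
bound-footprint targets of the knocked-down TF by a planted factor.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from cisgrn.core import GeneModel, Genome, GenomicInterval, SignalTrack
from cisgrn.enhancers import Peak
from cisgrn.expression import COMPARTMENTS
from cisgrn.grn import FootprintCall, RegulatoryLink, tss_of
from cisgrn.motifs import Motif, MotifTFMap
from cisgrn.validation import KnockdownExperiment

#: Dirichlet concentration parameters per enrichment class.
DEFAULT_CLASS_CONCENTRATIONS: Dict[str, Tuple[float, float, float]] = {
    "X1": (70, 15, 15),
    "X2": (15, 70, 15),
    "Xins": (15, 15, 70),
    "X1_X2": (100, 100, 38),
    "X1_Xins": (100, 38, 100),
    "X2_Xins": (38, 100, 100),
    "ubiquitous": (90, 90, 90),
}

#: Class frequencies, skewed toward Xins-containing classes.
DEFAULT_CLASS_FREQUENCIES: Dict[str, float] = {
    "X1": 0.10,
    "X2": 0.08,
    "Xins": 0.22,
    "X1_X2": 0.15,
    "X1_Xins": 0.05,
    "X2_Xins": 0.20,
    "ubiquitous": 0.20,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome / genes
    n_chroms: int = 3
    chrom_length: int = 500_000
    n_genes: int = 300
    tf_fraction: float = 0.25
    gene_length_mean: float = 1500.0
    gene_length_sd: float = 400.0
    min_gene_length: int = 300
    # enhancers and peaks
    n_enhancers: int = 200
    n_decoy_ac_peaks: int = 200
    n_decoy_me1_peaks: int = 200
    peak_width_mean: float = 180.0
    peak_width_sd: float = 30.0
    min_peak_width: int = 60
    max_gap: int = 500
    proximal_fraction: float = 0.4      # mass of the promoter-proximal component
    proximal_max_distance: int = 1000
    distal_tail_scale: float = 15_000.0  # exponential tail of TSS distances
    max_tss_distance: int = 90_000
    # tracks
    track_bin: int = 10
    track_noise_sd: float = 0.1
    # expression
    n_replicates: int = 2
    magnitude_log_mean: float = math.log(20.0)
    magnitude_log_sd: float = 1.0
    replicate_log_sd: float = 0.2
    class_frequencies: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES))
    class_concentrations: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CONCENTRATIONS))
    # motifs / footprints
    n_motifs: int = 40
    motif_tf_multiplicity: int = 2
    motif_length_min: int = 8
    motif_length_max: int = 12
    max_motifs_per_enhancer: int = 3
    footprint_width: int = 12
    bound_rate_in_enhancers: float = 0.7
    bound_rate_elsewhere: float = 0.1
    n_background_footprints: int = 400
    # knockdowns
    n_knockdowns: int = 8
    de_base_rate: float = 0.05
    planted_enrichment_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.planted_enrichment_factor < 1:
            raise ValueError("planted_enrichment_factor must be >= 1")
        for name in ("tf_fraction", "proximal_fraction", "bound_rate_in_enhancers",
                     "bound_rate_elsewhere", "de_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class GroundTruth:
    """Planted structure realised in the emitted files."""

    enhancers: List[dict] = field(default_factory=list)   # enhancer_id, coords, target
    adjacency: List[dict] = field(default_factory=list)   # tf, target, enhancer_id, bound
    gene_classes: Dict[str, str] = field(default_factory=dict)
    de_sets: Dict[str, List[str]] = field(default_factory=dict)
    tf_genes: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# genome and genes


def simulate_genome_genes(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Genome, List[GeneModel], GroundTruth]:
    rng = rng or np.random.default_rng(config.seed)
    genome = Genome({f"chr{i + 1}": config.chrom_length
                     for i in range(config.n_chroms)})
    per_chrom = _split_counts(config.n_genes, config.n_chroms)
    n_tf = int(round(config.tf_fraction * config.n_genes))
    tf_idx = set(rng.choice(config.n_genes, size=n_tf, replace=False).tolist())

    genes: List[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(genome.chrom_sizes):
        k = per_chrom[ci]
        lengths = np.maximum(
            config.min_gene_length,
            rng.normal(config.gene_length_mean, config.gene_length_sd, size=k),
        ).astype(np.int64)
        free = config.chrom_length - int(lengths.sum())
        if free <= k:
            raise ValueError("infeasible gene packing: genes exceed chromosome length")
        offsets = np.sort(rng.choice(free, size=k, replace=False))
        starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.choice(["+", "-"], size=k)
        for j in range(k):
            gene_id = f"g{gi:04d}"
            is_tf = gi in tf_idx
            genes.append(GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, int(starts[j]),
                                         int(starts[j] + lengths[j]),
                                         name=gene_id, strand=str(strands[j])),
                is_tf=is_tf,
                tf_name=f"tf_{gene_id}" if is_tf else None,
            ))
            gi += 1
    truth = GroundTruth(tf_genes=[g.gene_id for g in genes if g.is_tf])
    return genome, genes, truth


def _split_counts(total: int, parts: int) -> List[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# epigenome: peaks and tracks


def simulate_epigenome(
    config: SimulationConfig,
    genome: Genome,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Peak], List[Peak], Dict[str, SignalTrack]]:
    """Plant enhancers near gene TSSs; emit peak sets and five signal tracks.

    Returns (H3K27ac peaks, H3K4me1 peaks, tracks) where tracks has keys
    h3k27ac, h3k4me1, lpt_lfc, atac, fpscore.  Decoy peaks of each mark are
    kept > max_gap away from every peak of the other mark so they cannot
    qualify as enhancers.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    margin = 2000
    chroms = list(genome.chrom_sizes)

    target_idx = rng.choice(len(genes), size=config.n_enhancers,
                            replace=config.n_enhancers > len(genes))
    ac_peaks: List[Peak] = []
    me1_peaks: List[Peak] = []
    centers: List[Tuple[str, int]] = []

    for i, gidx in enumerate(target_idx):
        gene = genes[int(gidx)]
        chrom = gene.interval.chrom
        chrom_len = genome.chrom_sizes[chrom]
        if rng.random() < config.proximal_fraction:
            d = int(rng.integers(0, config.proximal_max_distance + 1))
        else:
            d = int(min(rng.exponential(config.distal_tail_scale),
                        config.max_tss_distance))
        side = 1 if rng.random() < 0.5 else -1
        center = int(np.clip(tss_of(gene) + side * d, margin, chrom_len - margin))
        w_ac = _peak_width(config, rng)
        ac_iv = GenomicInterval(chrom, max(0, center - w_ac // 2),
                                center - w_ac // 2 + w_ac, name=f"enh{i:04d}")
        w_me1 = _peak_width(config, rng)
        gap = int(rng.integers(0, config.max_gap + 1))
        if rng.random() < 0.5:
            me1_start = ac_iv.end + gap
        else:
            me1_start = ac_iv.start - gap - w_me1
        me1_start = max(0, min(me1_start, chrom_len - w_me1))
        me1_iv = GenomicInterval(chrom, me1_start, me1_start + w_me1,
                                 name=f"me1_true{i:04d}")
        ac_peaks.append(Peak(ac_iv, "H3K27ac", ac_iv.name))
        me1_peaks.append(Peak(me1_iv, "H3K4me1", me1_iv.name))
        centers.append((chrom, center))
        truth.enhancers.append({
            "enhancer_id": ac_iv.name,
            "chrom": chrom, "start": ac_iv.start, "end": ac_iv.end,
            "placed_near_gene": gene.gene_id,
            "target_gene": _nearest_tss_gene(ac_iv, genes),
        })

    # Decoys: single-mark peaks far (> max_gap) from every other-mark peak.
    me1_like = [p.interval for p in me1_peaks]
    for i in range(config.n_decoy_ac_peaks):
        iv = _place_away(config, genome, rng, me1_like, f"ac_decoy{i:04d}")
        ac_peaks.append(Peak(iv, "H3K27ac", iv.name))
    ac_like = [p.interval for p in ac_peaks]
    for i in range(config.n_decoy_me1_peaks):
        iv = _place_away(config, genome, rng, ac_like, f"me1_decoy{i:04d}")
        me1_peaks.append(Peak(iv, "H3K4me1", iv.name))

    tracks = _build_tracks(config, genome, rng, ac_peaks, me1_peaks, centers)
    return ac_peaks, me1_peaks, tracks


def _peak_width(config: SimulationConfig, rng: np.random.Generator) -> int:
    return int(max(config.min_peak_width,
                   rng.normal(config.peak_width_mean, config.peak_width_sd)))


def _nearest_tss_gene(iv: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """Brute-force nearest-TSS target, independent of the pipeline code."""
    best = None
    for g in genes:
        if g.interval.chrom != iv.chrom:
            continue
        tss = tss_of(g)
        if iv.start <= tss < iv.end:
            d = 0
        else:
            d = min(abs(tss - iv.start), abs(tss - (iv.end - 1)))
        key = (d, tss, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id)
    assert best is not None
    return best[1]


def _place_away(
    config: SimulationConfig,
    genome: Genome,
    rng: np.random.Generator,
    avoid: Sequence[GenomicInterval],
    name: str,
) -> GenomicInterval:
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.float64)
    avoid_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        ivs = [a for a in avoid if a.chrom == chrom]
        avoid_by_chrom[chrom] = (
            np.array([a.start for a in ivs]),
            np.array([a.end for a in ivs]),
        )
    for _ in range(10_000):
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[ci]
        w = _peak_width(config, rng)
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - w))
        starts, ends = avoid_by_chrom[chrom]
        if starts.size:
            gaps = np.maximum(0, np.maximum(starts - (start + w), start - ends))
            if gaps.min() <= config.max_gap:
                continue
        return GenomicInterval(chrom, start, start + w, name=name)
    raise RuntimeError("could not place a decoy peak away from the other mark")


def _build_tracks(
    config: SimulationConfig,
    genome: Genome,
    rng: np.random.Generator,
    ac_peaks: Sequence[Peak],
    me1_peaks: Sequence[Peak],
    enhancer_centers: Sequence[Tuple[str, int]],
) -> Dict[str, SignalTrack]:
    b = config.track_bin
    names = ("h3k27ac", "h3k4me1", "lpt_lfc", "atac", "fpscore")
    arrays: Dict[str, Dict[str, np.ndarray]] = {
        n: {c: np.zeros(genome.chrom_sizes[c] // b) for c in genome.chrom_sizes}
        for n in names
    }

    def bump(name: str, chrom: str, center: int, amp: float, sd: float) -> None:
        arr = arrays[name][chrom]
        c = center / b
        s = sd / b
        lo = max(0, int(c - 4 * s))
        hi = min(arr.size, int(c + 4 * s) + 1)
        x = np.arange(lo, hi)
        arr[lo:hi] += amp * np.exp(-0.5 * ((x - c) / s) ** 2)

    for p in ac_peaks:
        bump("h3k27ac", p.interval.chrom, p.interval.center, 3.0, len(p.interval) / 2)
    for p in me1_peaks:
        bump("h3k4me1", p.interval.chrom, p.interval.center, 2.0, len(p.interval) / 2)
    for chrom, center in enhancer_centers:
        # bimodal H3K4me1 flanks around the H3K27ac center
        bump("h3k4me1", chrom, center - 300, 2.0, 150)
        bump("h3k4me1", chrom, center + 300, 2.0, 150)
        bump("atac", chrom, center, 3.0, 150)
        bump("fpscore", chrom, center, 2.5, 150)
        bump("lpt_lfc", chrom, center, -1.5, 200)

    if config.track_noise_sd > 0:
        for name in names:
            for chrom in genome.chrom_sizes:
                arr = arrays[name][chrom]
                arr += rng.normal(0.0, config.track_noise_sd, size=arr.size)

    tracks: Dict[str, SignalTrack] = {}
    for name in names:
        per_chrom = {}
        for chrom in genome.chrom_sizes:
            arr = np.round(arrays[name][chrom], 4)
            nz = np.flatnonzero(arr != 0.0)
            per_chrom[chrom] = (nz * b, (nz + 1) * b, arr[nz])
        tracks[name] = SignalTrack.from_arrays(per_chrom)
    return tracks


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-sample TPM table with Dirichlet compartment structure.

    Each gene is drawn from one of the seven enrichment classes at the
    configured frequencies; its true class is recorded in the ground truth.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    classes = sorted(config.class_frequencies)
    freqs = np.array([config.class_frequencies[c] for c in classes], dtype=float)
    freqs /= freqs.sum()
    samples = [f"{comp}_r{r + 1}" for comp in COMPARTMENTS
               for r in range(config.n_replicates)]
    rows = []
    for g in genes:
        cls = classes[int(rng.choice(len(classes), p=freqs))]
        truth.gene_classes[g.gene_id] = cls
        props = rng.dirichlet(config.class_concentrations[cls])
        magnitude = float(rng.lognormal(config.magnitude_log_mean,
                                        config.magnitude_log_sd))
        row = {}
        for ci, comp in enumerate(COMPARTMENTS):
            for r in range(config.n_replicates):
                noise = float(rng.lognormal(0.0, config.replicate_log_sd))
                row[f"{comp}_r{r + 1}"] = props[ci] * magnitude * noise
        rows.append(row)
    df = pd.DataFrame(rows, index=[g.gene_id for g in genes])[samples]
    df.index.name = "gene_id"
    return df


def sample_compartment_map(config: SimulationConfig) -> Dict[str, str]:
    return {f"{comp}_r{r + 1}": comp for comp in COMPARTMENTS
            for r in range(config.n_replicates)}


# ---------------------------------------------------------------------------
# motifs, footprints, knockdown DE sets


def simulate_motifs(
    config: SimulationConfig,
    tf_gene_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Motif], MotifTFMap]:
    """Random PWMs plus a many-to-one TF -> motif assignment.

    Each TF is served by exactly one motif; each motif serves up to
    ``motif_tf_multiplicity`` TFs (paralog families sharing one matrix).
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    needed = math.ceil(len(tf_gene_ids) / max(1, config.motif_tf_multiplicity))
    if config.n_motifs < needed:
        raise ValueError(f"n_motifs={config.n_motifs} too small for "
                         f"{len(tf_gene_ids)} TFs at multiplicity "
                         f"{config.motif_tf_multiplicity}")
    motif_list = []
    for i in range(config.n_motifs):
        length = int(rng.integers(config.motif_length_min,
                                  config.motif_length_max + 1))
        pwm = rng.dirichlet([0.6, 0.6, 0.6, 0.6], size=length).T
        motif_list.append(Motif(motif_id=f"M{i:03d}", pwm=pwm))
    mapping = MotifTFMap()
    for j, tf in enumerate(sorted(tf_gene_ids)):
        mapping.add(motif_list[j // config.motif_tf_multiplicity].motif_id, tf)
    return motif_list, mapping


def simulate_footprints_and_rnai(
    config: SimulationConfig,
    genome: Genome,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    mapping: MotifTFMap,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[FootprintCall], Dict[str, Set[str]]]:
    """Plant footprints inside true enhancers and derive knockdown DE sets.

    For every planted footprint of a TF's motif inside an enhancer, all TFs
    mapped to that motif gain a (tf -> enhancer target) edge in the planted
    adjacency, with the footprint's bound flag.  DE sets make a bound
    target of the knocked-down TF differentially expressed with probability
    ``min(1, de_base_rate * planted_enrichment_factor)``; every other TF
    with ``de_base_rate``.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    tf_with_motif = sorted(mapping.tf_ids)
    motif_of_tf = {tf: mid for mid, tf in
                   ((m, t) for m, t in mapping.pairs())}
    footprints: List[FootprintCall] = []
    bound_targets: Dict[str, Set[str]] = {tf: set() for tf in tf_with_motif}
    fp_w = config.footprint_width
    fp_n = 0

    for rec in truth.enhancers:
        chrom, start, end = rec["chrom"], rec["start"], rec["end"]
        target = rec["target_gene"]
        n_mot = int(rng.integers(1, config.max_motifs_per_enhancer + 1))
        chosen = rng.choice(len(tf_with_motif), size=min(n_mot, len(tf_with_motif)),
                            replace=False)
        for t in chosen:
            tf = tf_with_motif[int(t)]
            motif_id = motif_of_tf[tf]
            pos = int(rng.integers(start, max(start + 1, end - fp_w)))
            bound = bool(rng.random() < config.bound_rate_in_enhancers)
            footprints.append(FootprintCall(
                interval=GenomicInterval(chrom, pos, pos + fp_w, name=f"fp{fp_n:05d}"),
                motif_id=motif_id,
                score=float(np.round(rng.normal(8.0 if bound else 3.0, 1.0), 3)),
                bound=bound,
            ))
            fp_n += 1
            for linked_tf in mapping.tfs_for(motif_id):
                truth.adjacency.append({
                    "tf": linked_tf, "target": target,
                    "enhancer_id": rec["enhancer_id"], "bound": bound,
                })
                if bound:
                    bound_targets[linked_tf].add(target)

    # Background footprints outside any true enhancer.
    enh_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for rec in truth.enhancers:
        enh_by_chrom.setdefault(rec["chrom"], []).append((rec["start"], rec["end"]))
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.float64)
    motif_ids = mapping.motif_ids
    placed = 0
    attempts = 0
    while placed < config.n_background_footprints and attempts < 100_000:
        attempts += 1
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[ci]
        pos = int(rng.integers(0, genome.chrom_sizes[chrom] - fp_w))
        if any(s < pos + fp_w and pos < e for s, e in enh_by_chrom.get(chrom, ())):
            continue
        bound = bool(rng.random() < config.bound_rate_elsewhere)
        footprints.append(FootprintCall(
            interval=GenomicInterval(chrom, pos, pos + fp_w, name=f"fp{fp_n:05d}"),
            motif_id=motif_ids[int(rng.integers(0, len(motif_ids)))],
            score=float(np.round(rng.normal(8.0 if bound else 3.0, 1.0), 3)),
            bound=bound,
        ))
        fp_n += 1
        placed += 1

    # Knockdown DE sets over the TF universe.
    tf_universe = sorted(truth.tf_genes)
    n_bound = {tf: len(bound_targets.get(tf, ()))
               for tf in tf_with_motif}
    ranked = sorted(tf_with_motif, key=lambda tf: (-n_bound[tf], tf))
    knockdowns = ranked[:config.n_knockdowns]
    de_sets: Dict[str, Set[str]] = {}
    p_hi = min(1.0, config.de_base_rate * config.planted_enrichment_factor)
    for kd in knockdowns:
        targets = bound_targets.get(kd, set())
        de = set()
        for tf in tf_universe:
            p = p_hi if tf in targets else config.de_base_rate
            if rng.random() < p:
                de.add(tf)
        de_sets[kd] = de
        truth.de_sets[kd] = sorted(de)
    return footprints, de_sets


# ---------------------------------------------------------------------------
# full dataset emission


def simulate_all(config: SimulationConfig):
    """Generate every pipeline input in memory.

    Returns a dict with genome, genes, peaks, tracks, expression table,
    motifs, motif->TF map, footprints, DE sets, and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    genome, genes, truth = simulate_genome_genes(config, rng)
    ac, me1, tracks = simulate_epigenome(config, genome, genes, truth, rng)
    expr = simulate_expression(config, genes, truth, rng)
    motif_list, mapping = simulate_motifs(
        config, [g.gene_id for g in genes if g.is_tf], rng)
    footprints, de_sets = simulate_footprints_and_rnai(
        config, genome, genes, truth, mapping, rng)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "ac_peaks": ac,
        "me1_peaks": me1,
        "tracks": tracks,
        "expression": expr,
        "motifs": motif_list,
        "motif_tf_map": mapping,
        "footprints": footprints,
        "de_sets": de_sets,
        "truth": truth,
    }


def emit_dataset(config: SimulationConfig, outdir) -> dict:
    """Write the full synthetic dataset as plain-text files.

    Emits: genome.sizes, genes.gtf, expr.tsv, ac.bed, me1.bed, five
    bedGraph tracks, footprints.tsv, motifs.jaspar, motif_tf_map.tsv,
    rnai_de.tsv, truth.json.  Byte-identical for a given config.
    """
    from cisgrn import io  # local import to avoid a cycle at module load

    data = simulate_all(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_chrom_sizes(data["genome"], outdir / "genome.sizes")
    io.write_gtf_genes(data["genes"], outdir / "genes.gtf")
    io.write_expression_table(data["expression"], outdir / "expr.tsv")
    io.write_bed([p.interval for p in data["ac_peaks"]], outdir / "ac.bed")
    io.write_bed([p.interval for p in data["me1_peaks"]], outdir / "me1.bed")
    for name, track in data["tracks"].items():
        io.write_bedgraph(track, outdir / f"{name}.bedgraph")
    io.write_footprints(data["footprints"], outdir / "footprints.tsv")
    io.write_jaspar(data["motifs"], outdir / "motifs.jaspar")
    io.write_motif_tf_map(data["motif_tf_map"], outdir / "motif_tf_map.tsv")
    io.write_de_lists(data["de_sets"], outdir / "rnai_de.tsv")
    data["truth"].to_json(outdir / "truth.json")
    return data


# ---------------------------------------------------------------------------
# lightweight link cohorts for statistical calibration


@dataclass
class LinkCohortConfig:
    """Abstract (genome-free) cohort of knockdowns for calibration runs."""

    seed: int = 0
    n_tfs: int = 1000
    n_knockdowns: int = 8
    bound_targets_per_kd: int = 60
    unbound_targets_per_kd: int = 60
    extra_cis_tfs: int = 100
    de_base_rate: float = 0.2
    planted_enrichment_factor: float = 1.0


def simulate_link_cohort(
    cfg: LinkCohortConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Set[str], List[RegulatoryLink], List[KnockdownExperiment]]:
    """Links + DE sets with the same statistical model as the full simulator.

    Bound targets of the knocked-down TF are differentially expressed with
    probability ``min(1, de_base_rate * planted_enrichment_factor)``; every
    other TF with ``de_base_rate``.  Used for null calibration and
    enrichment-factor recovery at sizes where a full genome simulation
    would be wasteful.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    universe = [f"tf{i:04d}" for i in range(cfg.n_tfs)]
    kd_tfs = [universe[i] for i in
              rng.choice(cfg.n_tfs, size=cfg.n_knockdowns, replace=False)]
    links: List[RegulatoryLink] = []
    experiments: List[KnockdownExperiment] = []
    p_hi = min(1.0, cfg.de_base_rate * cfg.planted_enrichment_factor)

    # extra cis-linked TFs so ncis is realistic (linked by a pseudo-TF hub)
    extra = rng.choice(cfg.n_tfs, size=cfg.extra_cis_tfs, replace=False)
    for j, t in enumerate(extra):
        links.append(RegulatoryLink(
            tf_gene_id=universe[int(rng.integers(0, cfg.n_tfs))],
            target_gene_id=universe[int(t)],
            enhancer_id=f"xenh{j}", bound=True, motif_id="MX",
        ))

    for kd in kd_tfs:
        n_t = cfg.bound_targets_per_kd + cfg.unbound_targets_per_kd
        picks = rng.choice(cfg.n_tfs, size=n_t, replace=False)
        bound_t = {universe[int(i)] for i in picks[:cfg.bound_targets_per_kd]}
        unbound_t = {universe[int(i)] for i in picks[cfg.bound_targets_per_kd:]}
        for j, t in enumerate(sorted(bound_t)):
            links.append(RegulatoryLink(kd, t, f"{kd}_b{j}", True, "MB"))
        for j, t in enumerate(sorted(unbound_t)):
            links.append(RegulatoryLink(kd, t, f"{kd}_u{j}", False, "MU"))
        de = {tf for tf in universe
              if rng.random() < (p_hi if tf in bound_t else cfg.de_base_rate)}
        experiments.append(KnockdownExperiment.make(kd, sorted(de)))
    return set(universe), links, experiments
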
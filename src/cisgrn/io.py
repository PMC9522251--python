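"""Readers and writers for the plain-text formats the pipeline touches.

BED, bedGraph, GTF (gene skeletons only), footprint call tables, expression
TSV, motif->TF maps, knockdown DE lists, JASPAR PWMs, and chrom.sizes files.

Hand-rolled line parsers are used deliberately for the interval formats so
that malformed input can be reported with a line number, which the pipeline
contracts require; JASPAR parsing is delegated to Biopython.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from cisgrn.core import GeneModel, Genome, GenomicInterval, SignalTrack
from cisgrn.grn import FootprintCall
from cisgrn.motifs import Motif, MotifTFMap

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _fail(path: PathLike, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: PathLike) -> Genome:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                _fail(path, lineno, "expected 2 tab-separated fields")
            try:
                length = int(fields[1])
            except ValueError:
                _fail(path, lineno, f"non-integer length {fields[1]!r}")
            if fields[0] in sizes:
                _fail(path, lineno, f"duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = length
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED3/BED6 into 0-based half-open intervals.

    Name (column 4) is preserved when present; strand comes from column 6
    when present, else ".".
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, "expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}")
            if start < 0 or start >= end:
                _fail(path, lineno, f"invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(fields[0], start, end, name=name, strand=strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike,
              scores: Mapping[str, float] | None = None) -> None:
    """Write BED6; score column taken from ``scores`` by interval name (else 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if scores is None else scores.get(iv.name, 0)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: PathLike) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping steps are an error; gaps read back as signal 0.
    """
    # Fast path for well-formed files; falls back to the line-by-line
    # parser (which reports line numbers) on any typing problem.
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "value": np.float64},
        )
    except (ValueError, pd.errors.ParserError):
        return _read_bedgraph_slow(path)
    if df["chrom"].str.startswith(("track", "browser")).any():
        return _read_bedgraph_slow(path)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        return _read_bedgraph_slow(path)  # produce a line-numbered error
    per_chrom = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        per_chrom[str(chrom)] = (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
            sub["value"].to_numpy()[order],
        )
    return SignalTrack.from_arrays(per_chrom)


def _read_bedgraph_slow(path: PathLike) -> SignalTrack:
    track = SignalTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, "expected 4 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}")
            try:
                value = float(fields[3])
            except ValueError:
                _fail(path, lineno, f"non-numeric value {fields[3]!r}")
            if start < 0 or start >= end:
                _fail(path, lineno, f"invalid step [{start}, {end})")
            track.add_step(fields[0], start, end, value)
    return track.freeze()


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# GTF gene skeletons


def read_gtf_genes(path: PathLike) -> List[GeneModel]:
    """Collapse GTF records into one gene-level model per gene_id.

    The gene interval spans min(start)-1 .. max(end) of its records,
    converted from 1-based inclusive to 0-based half-open.  Strandless
    genes are rejected because the TSS would be undefined.
    """
    spans: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                _fail(path, lineno, "expected 9 tab-separated GTF fields")
            chrom, _source, _feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {start_s!r}, {end_s!r}")
            gene_id = _gtf_attr(attrs, "gene_id")
            if gene_id is None:
                _fail(path, lineno, "record without gene_id attribute")
            if strand not in ("+", "-"):
                _fail(path, lineno, f"gene {gene_id} has strand {strand!r}; TSS undefined")
            rec = spans.get(gene_id)
            if rec is None:
                spans[gene_id] = {
                    "chrom": chrom, "start": start1 - 1, "end": end1, "strand": strand,
                    "is_tf": _gtf_attr(attrs, "is_tf") == "1",
                    "tf_name": _gtf_attr(attrs, "tf_name"),
                }
                order.append(gene_id)
            else:
                if rec["chrom"] != chrom or rec["strand"] != strand:
                    _fail(path, lineno, f"gene {gene_id} spans chromosomes or strands")
                rec["start"] = min(rec["start"], start1 - 1)
                rec["end"] = max(rec["end"], end1)
    genes = []
    for gene_id in order:
        rec = spans[gene_id]
        genes.append(GeneModel(
            gene_id=gene_id,
            interval=GenomicInterval(rec["chrom"], rec["start"], rec["end"],
                                     name=gene_id, strand=rec["strand"]),
            is_tf=rec["is_tf"],
            tf_name=rec["tf_name"],
        ))
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


def write_gtf_genes(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write one gene-level GTF record per gene (1-based inclusive coords)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; is_tf "{1 if g.is_tf else 0}";'
            if g.tf_name:
                attrs += f' tf_name "{g.tf_name}";'
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tcisgrn\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Footprint call tables (BINDetect-style)


def read_footprints(path: PathLike) -> List[FootprintCall]:
    """Read a footprint table: chrom, start, end, motif_id, score, bound(0/1)."""
    calls: List[FootprintCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # optional header
                continue
            if len(fields) < 6:
                _fail(path, lineno, "expected 6 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}")
            if start < 0:
                _fail(path, lineno, f"negative coordinate {start}")
            try:
                score = float(fields[4])
            except ValueError:
                _fail(path, lineno, f"non-numeric score {fields[4]!r}")
            if fields[5] not in ("0", "1"):
                _fail(path, lineno, f"bound flag must be 0 or 1, got {fields[5]!r}")
            calls.append(FootprintCall(
                interval=GenomicInterval(fields[0], start, end, name=f"fp{lineno}"),
                motif_id=fields[3],
                score=score,
                bound=fields[5] == "1",
            ))
    return calls


def write_footprints(calls: Iterable[FootprintCall], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmotif_id\tscore\tbound\n")
        for c in calls:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.motif_id}\t{c.score:.6g}\t{1 if c.bound else 0}\n"
            )


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path: PathLike) -> pd.DataFrame:
    """Per-sample TPM table: gene_id column + one numeric column per sample."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing gene_id column")
    return df.set_index("gene_id")


def write_expression_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Motif -> TF map and DE lists


def read_motif_tf_map(path: PathLike) -> MotifTFMap:
    df = pd.read_csv(path, sep="\t")
    for col in ("motif_id", "tf_gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return MotifTFMap.from_pairs(zip(df["motif_id"], df["tf_gene_id"]))


def write_motif_tf_map(mapping: MotifTFMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttf_gene_id\n")
        for motif_id, tf in mapping.pairs():
            fh.write(f"{motif_id}\t{tf}\n")


def read_de_lists(path: PathLike) -> Dict[str, set]:
    """Knockdown DE lists TSV (knockdown_tf, gene_id) -> {knockdown: set of genes}."""
    df = pd.read_csv(path, sep="\t")
    for col in ("knockdown_tf", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out: Dict[str, set] = {}
    for kd, gene in zip(df["knockdown_tf"], df["gene_id"]):
        out.setdefault(kd, set())
        if gene != ".":  # "." marks a knockdown with an empty DE set
            out[kd].add(gene)
    return out


def write_de_lists(de_sets: Mapping[str, Iterable[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("knockdown_tf\tgene_id\n")
        for kd in sorted(de_sets):
            genes = sorted(de_sets[kd])
            if not genes:
                fh.write(f"{kd}\t.\n")
            for gene in genes:
                fh.write(f"{kd}\t{gene}\n")


# ---------------------------------------------------------------------------
# JASPAR PWMs


def read_jaspar(path: PathLike) -> List[Motif]:
    """Read JASPAR-format matrices; counts are normalised per column on load."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        out = []
        for rec in records:
            counts = np.array([rec.counts[base] for base in "ACGT"], dtype=np.float64)
            colsums = counts.sum(axis=0)
            if np.any(colsums <= 0):
                raise ParseError(f"{path}: motif {rec.matrix_id} has an all-zero column")
            out.append(Motif(motif_id=rec.matrix_id or rec.name, pwm=counts / colsums))
    return out


def write_jaspar(motif_list: Sequence[Motif], path: PathLike, scale: int = 1000) -> None:
    """Write motifs as JASPAR count matrices (probabilities scaled to counts)."""
    buf = _stdio.StringIO()
    for m in motif_list:
        buf.write(f">{m.motif_id}\t{m.motif_id}\n")
        for i, base in enumerate("ACGT"):
            row = " ".join(f"{int(round(p * scale)):6d}" for p in m.pwm[i])
            buf.write(f"{base}  [{row} ]\n")
    Path(path).write_text(buf.getvalue())
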
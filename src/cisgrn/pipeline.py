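"""End-to-end pipeline: dataset directory in, analysis tables out.

Reads the plain-text inputs emitted by the simulator (or prepared from
real processed data in the same formats), then runs enhancer calling,
expression profiling, signal tests, network construction, and knockdown
validation.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from cisgrn import io
from cisgrn.enhancers import call_enhancers, random_regions, region_signal_test, Peak
from cisgrn.expression import profiles_table, profile_genes, summarize_compartments
from cisgrn.grn import assign_targets, build_links, links_table_rows, subnetwork_x1
from cisgrn.validation import KnockdownExperiment, cohort_summary, oe_ratio, permutation_p

DEFAULT_N_RANDOM_REGIONS = 10_000
DEFAULT_RANDOM_REGION_LENGTH = 500


def run_pipeline(
    indir,
    outdir,
    *,
    seed: int = 0,
    max_gap: int = 500,
    n_perm: int = 1000,
    n_random_regions: int = DEFAULT_N_RANDOM_REGIONS,
    random_region_length: int = DEFAULT_RANDOM_REGION_LENGTH,
    x1_threshold: float = 1.0 / 3.0,
) -> dict:
    """Run every stage; writes TSV/BED outputs into ``outdir``.

    Expects in ``indir``: genome.sizes, genes.gtf, expr.tsv, ac.bed,
    me1.bed, atac.bedgraph, lpt_lfc.bedgraph, footprints.tsv,
    motif_tf_map.tsv, rnai_de.tsv.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = io.read_chrom_sizes(indir / "genome.sizes")
    genes = io.read_gtf_genes(indir / "genes.gtf")
    ac = [Peak(iv, "H3K27ac", iv.name) for iv in io.read_bed(indir / "ac.bed")]
    me1 = [Peak(iv, "H3K4me1", iv.name) for iv in io.read_bed(indir / "me1.bed")]

    # --- enhancer calling
    enhancers = call_enhancers(ac, me1, max_gap=max_gap)
    io.write_bed([e.interval for e in enhancers], outdir / "enhancers.bed",
                 scores={e.enhancer_id: e.gap_bp for e in enhancers})

    # --- signal at enhancers vs random background
    rand = random_regions(genome, n_random_regions, random_region_length, seed)
    signal_rows = []
    for track_name, expect in (("atac", "higher"), ("lpt_lfc", "lower")):
        path = indir / f"{track_name}.bedgraph"
        if not path.exists():
            continue
        track = io.read_bedgraph(path)
        va, vb, stat, p = region_signal_test(
            track, [e.interval for e in enhancers], rand)
        signal_rows.append({
            "track": track_name,
            "n_enhancers": len(va), "n_random": len(vb),
            "enhancer_median": float(pd.Series(va).median()),
            "random_median": float(pd.Series(vb).median()),
            "statistic": stat, "p_value": p, "expected_direction": expect,
        })
    pd.DataFrame(signal_rows).to_csv(outdir / "signal_tests.tsv", sep="\t",
                                     index=False, float_format="%.6g")

    # --- expression profiles
    expr = io.read_expression_table(indir / "expr.tsv")
    sample_map = {s: s.split("_")[0] for s in expr.columns}
    comp = summarize_compartments(expr, sample_map)
    ptable = profiles_table(comp)
    ptable.to_csv(outdir / "profiles.tsv", sep="\t", index=False,
                  float_format="%.6g")
    profiles, _ = profile_genes(comp)
    prof_by_id = {p.gene_id: p for p in profiles}
    tpm_x1 = {e.gene_id: e.tpm_x1 for e in comp}

    # --- targets and links
    assignments = assign_targets(enhancers, genes)
    footprints = io.read_footprints(indir / "footprints.tsv")
    mapping = io.read_motif_tf_map(indir / "motif_tf_map.tsv")
    tf_genes = {g.gene_id for g in genes if g.is_tf}
    links = build_links(enhancers, assignments, footprints, mapping, tf_genes)
    pd.DataFrame(links_table_rows(links, assignments)).to_csv(
        outdir / "links.tsv", sep="\t", index=False)

    # --- X1 subnetwork
    grn = subnetwork_x1(links, prof_by_id, tpm_x1, threshold=x1_threshold)
    nodes = pd.DataFrame(
        [{"gene_id": n, **grn.nodes[n]} for n in sorted(grn.nodes)])
    edges = pd.DataFrame(
        [{"tf_gene_id": u, "target_gene_id": v, **grn.edges[u, v]}
         for u, v in sorted(grn.edges)])
    nodes.to_csv(outdir / "grn_nodes.tsv", sep="\t", index=False,
                 float_format="%.6g")
    edges.to_csv(outdir / "grn_edges.tsv", sep="\t", index=False)

    # --- knockdown validation
    results = []
    de_sets = io.read_de_lists(indir / "rnai_de.tsv")
    for i, kd in enumerate(sorted(de_sets)):
        if kd not in tf_genes:
            continue
        exp = KnockdownExperiment.make(kd, sorted(de_sets[kd] & tf_genes))
        res = oe_ratio(exp, links, tf_genes)
        pvals = permutation_p(exp, links, tf_genes, n_perm=n_perm, seed=seed + 1 + i)
        for cls, p in pvals.items():
            res.by_class[cls].p_perm = p
        results.append(res)
    if results:
        means, table = cohort_summary(results)
        table.to_csv(outdir / "validation.tsv", sep="\t", index=False,
                     float_format="%.6g")
        with open(outdir / "validation_summary.tsv", "w") as fh:
            fh.write("class\tmean_ratio\n")
            for cls in ("unbound", "bound"):
                v = means[cls]
                fh.write(f"{cls}\t{'NA' if v is None else format(v, '.6g')}\n")
    else:
        means, table = {}, pd.DataFrame()

    return {
        "enhancers": enhancers,
        "assignments": assignments,
        "links": links,
        "grn": grn,
        "profiles": profiles,
        "validation_results": results,
        "cohort_means": means,
        "signal_tests": pd.DataFrame(signal_rows),
    }
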
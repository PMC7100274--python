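"""End-to-end pipeline over maintainer/CMS genome pairs.

``run_pipeline`` executes every analysis stage on a configured set of
genomes — repeat landscape, synteny and rearrangement typing, conserved
gene clusters, ORF specificity screen, candidate-gene polymorphisms,
CMS-specific regions, and both phylogenies — and writes machine-readable
tables (TSV), interval files (BED/GFF3), newick trees and a run-metadata
record into an output directory. Every numeric cell is produced by the
corresponding library call; the pipeline adds no computation of its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from mitocompare import genome_io
from mitocompare.clusters import (
    conserved_clusters,
    detect_clusters,
    gene_overlaps,
    map_clusters_to_blocks,
)
from mitocompare.genes import call_polymorphisms, copy_numbers, intersect_candidates
from mitocompare.genome_io import CircularGenome, gc_content
from mitocompare.orfs import find_orfs, screen_specific_orfs, shared_specific_orfs
from mitocompare.phylo import (
    bootstrap_support,
    gene_concat_matrix,
    nj_tree,
    snp_matrix,
)
from mitocompare.repeats import (
    find_dispersed_repeats,
    find_ssrs,
    fraction_aligned_to,
    summarize_repeats,
)
from mitocompare.synteny import (
    aligned_fraction,
    build_synteny_blocks,
    classify_blocks,
    find_unique_regions,
)

log = logging.getLogger("mitocompare")


@dataclass
class RunConfig:
    """Pairing and parameters for one pipeline run.

    ``pairs``: list of (maintainer_id, cms_id); ``cultivar_of`` labels each
    pair. Defaults mirror the documented thresholds: repeat identity > 0.90
    (strict), ORF specificity < 0.99 (strict), ORFs > 300 nt, synteny
    blocks >= 3 kb, SSR motifs 1-6 bp.
    """

    pairs: list[tuple[str, str]]
    reference_id: str | None = None
    out_dir: str = "results/pipeline"
    min_repeat_identity: float = 0.90
    min_block: int = 3000
    orf_min_len: int = 300
    orf_sim_threshold: float = 0.99
    cluster_max_gap: int = 2000
    bootstrap_reps: int = 200
    seed: int = 0
    candidate_genes: list[str] | None = None
    assumed_defaults: dict = field(default_factory=lambda: {
        "dispersed_repeat_min_len": 20,
        "ssr_min_copies": "MISA-style {1:12,2:6,3:4,4:3,5:3,6:3}",
        "cluster_max_gap": 2000,
    })


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(genomes: dict[str, CircularGenome], config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    gids = [g for pair in config.pairs for g in pair]

    # --- per-genome feature summary (genome size, GC, coding, repeats) ---
    repeats = {}
    ssrs = {}
    orfs = {}
    rows = {}
    for gid in gids:
        g = genomes[gid]
        repeats[gid] = find_dispersed_repeats(g, min_identity=config.min_repeat_identity)
        ssrs[gid] = find_ssrs(g)
        orfs[gid] = find_orfs(g, config.orf_min_len)
        summ = summarize_repeats(g, repeats[gid], ssrs[gid])
        coding = sum(f.length for f in g.genes if f.kind == "protein")
        rows[gid] = {
            "genome_size_bp": g.length,
            "gc_percent": round(100 * gc_content(g), 2),
            "protein_coding_genes": len({
                (f.name, f.part_suffix if genome_io.is_copy_label(f.part_suffix) else None)
                for f in g.genes if f.kind == "protein"
            }),
            "coding_bp": coding,
            "coding_percent": round(100 * coding / g.length, 2),
            "repeat_bp": summ.total_repeat_bp,
            "repeat_percent": round(100 * summ.repeat_fraction, 2),
            "n_dispersed_repeats": len(repeats[gid]),
            "n_ssrs": len(ssrs[gid]),
            "n_orfs": len(orfs[gid]),
            "gene_features": len(g.genes),
        }
    summary = pd.DataFrame(rows)
    _write_tsv(summary, out / "summary_features.tsv")
    results["summary"] = summary

    rep_rows = []
    bed_rows = []
    for gid in gids:
        for p in repeats[gid]:
            rep_rows.append(dict(genome=gid, start1=p.interval_1[0], end1=p.interval_1[1],
                                 start2=p.interval_2[0], end2=p.interval_2[1],
                                 orientation=p.orientation, size_class=p.size_class,
                                 length=p.length, identity=round(p.identity, 4),
                                 palindromic=p.palindromic))
            for t, iv in enumerate((p.interval_1, p.interval_2)):
                bed_rows.append((gid, iv[0], iv[1], f"{p.orientation}_{p.length}bp_arm{t+1}"))
    _write_tsv(pd.DataFrame(rep_rows), out / "repeats.tsv", index=False)
    genome_io.write_bed(sorted(bed_rows), out / "repeats.bed")
    ssr_rows = [
        dict(genome=gid, motif=r.motif, copies=r.copies, start=r.start, end=r.end,
             motif_class=r.motif_class)
        for gid in gids for r in ssrs[gid]
    ]
    _write_tsv(pd.DataFrame(ssr_rows), out / "ssrs.tsv", index=False)

    # --- copy numbers / conserved genes ---
    cn = copy_numbers([genomes[g] for g in gids])
    _write_tsv(cn, out / "copy_numbers.tsv")
    conserved_genes = sorted(cn.index[(cn > 0).all(axis=1)])
    (out / "conserved_genes.tsv").write_text(
        "\n".join(conserved_genes) + "\n"
    )
    results["copy_numbers"] = cn
    results["conserved_genes"] = conserved_genes

    # --- synteny per pair ---
    blocks_by_cms = {}
    blocks_by_maint = {}
    block_rows = []
    frac_rows = {}
    for maint_id, cms_id in config.pairs:
        blocks = classify_blocks(
            build_synteny_blocks(genomes[maint_id], genomes[cms_id],
                                 min_block=config.min_block)
        )
        blocks_by_maint[maint_id] = blocks
        # CMS-side view for region extraction and cluster context
        cms_blocks = classify_blocks(
            build_synteny_blocks(genomes[cms_id], genomes[maint_id],
                                 min_block=config.min_block)
        )
        blocks_by_cms[cms_id] = cms_blocks
        for b in blocks:
            block_rows.append(dict(
                maintainer=maint_id, cms=cms_id, m_start=b.a_start, m_end=b.a_end,
                c_start=b.b_start, c_end=b.b_end, orientation=b.orientation,
                identity=round(b.identity, 4), rearrangement=b.rearrangement_class,
            ))
        frac_rows[f"{maint_id}|{cms_id}"] = {
            "maintainer_aligned_percent": round(
                aligned_fraction(blocks, "a", genomes[maint_id].length), 2),
            "cms_aligned_percent": round(
                aligned_fraction(blocks, "b", genomes[cms_id].length), 2),
            "n_blocks": len(blocks),
        }
    _write_tsv(pd.DataFrame(block_rows), out / "synteny_blocks.tsv", index=False)
    genome_io.write_bed(
        sorted((r["maintainer"], r["m_start"], r["m_end"], r["rearrangement"])
               for r in block_rows),
        out / "blocks.bed",
    )
    _write_tsv(pd.DataFrame(frac_rows), out / "aligned_fractions.tsv")
    results["blocks"] = blocks_by_maint
    results["aligned_fractions"] = frac_rows

    # --- gene clusters ---
    cluster_genomes = [genomes[g] for g in gids]
    clusters_per = {g.id: detect_clusters(g, config.cluster_max_gap)
                    for g in cluster_genomes}
    conserved = conserved_clusters(cluster_genomes, clusters_per)
    map_clusters_to_blocks(conserved, blocks_by_cms)
    cl_rows = []
    for cc in conserved:
        row = dict(signature=cc.name)
        for gid in gids:
            s, e = cc.instances[gid]
            ctx = cc.block_context.get(gid, "")
            row[gid] = f"{s}-{e}" + (f" ({ctx})" if ctx else "")
        cl_rows.append(row)
    _write_tsv(pd.DataFrame(cl_rows), out / "gene_clusters.tsv", index=False)
    results["conserved_clusters"] = conserved
    overlaps = {gid: gene_overlaps(genomes[gid]) for gid in gids}
    results["gene_overlaps"] = overlaps
    _write_tsv(
        pd.DataFrame([dict(genome=g, gene_a=a, gene_b=b, overlap_bp=o)
                      for g, lst in overlaps.items() for a, b, o in lst]),
        out / "gene_overlaps.tsv", index=False,
    )

    # --- candidate genes ---
    poly = {}
    poly_rows = []
    for maint_id, cms_id in config.pairs:
        cultivar = f"{maint_id}|{cms_id}"
        recs = call_polymorphisms(genomes[maint_id], genomes[cms_id], cultivar)
        poly[cultivar] = recs
        for r in recs:
            for e in r.events:
                poly_rows.append(dict(
                    cultivar=cultivar, gene=r.gene, length_maintainer=r.length_a,
                    length_cms=r.length_b, event=e.format_table(),
                    synonymy=e.synonymy,
                ))
    _write_tsv(pd.DataFrame(poly_rows), out / "polymorphisms.tsv", index=False)
    candidates = intersect_candidates(list(poly.values())) if len(poly) > 1 else []
    results["polymorphisms"] = poly
    results["candidate_genes"] = candidates
    (out / "candidate_genes.tsv").write_text("\n".join(candidates) + "\n")

    # --- CMS-specific ORFs ---
    specific = {}
    for maint_id, cms_id in config.pairs:
        specific[cms_id] = screen_specific_orfs(
            genomes[cms_id], genomes[maint_id], config.orf_min_len,
            config.orf_sim_threshold, orfs=orfs[cms_id],
        )
    orf_rows = [
        dict(genome=cid, id=o.id, start=o.start, end=o.end, strand=o.strand,
             nt_length=o.nt_length, aa_length=o.aa_length)
        for cid, lst in specific.items() for o in lst
    ]
    _write_tsv(pd.DataFrame(orf_rows), out / "specific_orfs.tsv", index=False)
    shared = None
    if len(specific) > 1:
        shared = shared_specific_orfs(specific, config.orf_sim_threshold)
        (out / "shared_specific_orfs.tsv").write_text(
            "\n".join(sorted(p[list(p)[0]].id or "" for p in shared.shared)) + "\n"
        )
    else:
        log.info("single pair: cross-cultivar ORF intersection skipped")
    results["specific_orfs"] = specific
    results["shared_orfs"] = shared

    # --- CMS-specific regions ---
    cms_ids = [c for _m, c in config.pairs]
    regions = find_unique_regions(
        [genomes[c] for c in cms_ids],
        [genomes[m] for m, _c in config.pairs],
        min_len=config.min_block,
        blocks_by_cms=blocks_by_cms,
    )
    reg_rows = [
        dict(genome=r.genome_id, start=r.start, end=r.end, length=r.length,
             shared=r.shared, n_genes=len(r.genes), n_orfs=len(r.orfs))
        for r in regions
    ]
    _write_tsv(pd.DataFrame(reg_rows), out / "cms_region_report.tsv", index=False)
    genome_io.write_bed(
        sorted((r.genome_id, r.start, r.end, "shared" if r.shared else "private")
               for r in regions),
        out / "cms_regions.bed",
    )
    results["regions"] = regions

    # --- phylogenies ---
    trees = {}
    if len(config.pairs) > 1:
        cand = config.candidate_genes or candidates
        if cand:
            from mitocompare.genes import gene_copies

            seqs = {}
            for gid in gids:
                cp = gene_copies(genomes[gid])
                if all(g in cp for g in cand):
                    seqs[gid] = {g: cp[g][0][1] for g in cand}
            mat = gene_concat_matrix(seqs, cand)
            mp = bootstrap_support(mat, "mp", config.bootstrap_reps, config.seed)
            trees["gene_mp"] = mp
            (out / "tree_candidate_genes_mp.nwk").write_text(
                mp.to_newick(with_supports=True) + "\n")
    if config.reference_id is not None:
        mat = snp_matrix([genomes[g] for g in gids], genomes[config.reference_id])
        njt = bootstrap_support(mat, "nj", config.bootstrap_reps, config.seed)
        trees["snp_nj"] = njt
        (out / "tree_snp_nj.nwk").write_text(njt.to_newick(with_supports=True) + "\n")
        results["snp_matrix_columns"] = mat.n_columns
    results["trees"] = trees

    # --- chloroplast-derived / cross-line fractions, metadata ---
    meta = dict(
        parameters=dict(
            min_repeat_identity=config.min_repeat_identity,
            min_block=config.min_block,
            orf_min_len=config.orf_min_len,
            orf_sim_threshold=config.orf_sim_threshold,
            cluster_max_gap=config.cluster_max_gap,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
        ),
        assumed_defaults=config.assumed_defaults,
        pairs=config.pairs,
        reference=config.reference_id,
    )
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    for gid in gids:
        genome_io.write_gff3(genomes[gid], out / f"{gid}.gff3")
    results["out_dir"] = str(out)
    return results
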
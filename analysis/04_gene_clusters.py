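"""Conserved gene clusters and overlapping gene pairs.

Detects runs of neighboring genes (gap <= 2 kb) in each genome, intersects
the cluster signatures across all four genomes (orientation-normalized,
sub-run aware), locates each conserved cluster inside the synteny-block
classes of its CMS genome, and reports overlapping gene pairs — the
rpl16/rps3 pair overlaps by the same 108 bp in every genome.
"""

from pathlib import Path

import pandas as pd

from mitocompare.clusters import (
    conserved_clusters,
    detect_clusters,
    gene_overlaps,
    map_clusters_to_blocks,
)
from mitocompare.genome_io import attach_gff3, read_fasta
from mitocompare.synteny import build_synteny_blocks, classify_blocks

GENOMES = ["A_maint", "A_cms", "B_maint", "B_cms"]
PAIRS = [("A_maint", "A_cms"), ("B_maint", "B_cms")]
IN = Path("results/genomes")
OUT = Path("results")


def load(gid):
    g = read_fasta(IN / f"{gid}.fasta")[0]
    g.id = gid
    return attach_gff3(g, IN / f"{gid}.gff3")


def main() -> None:
    genomes = {gid: load(gid) for gid in GENOMES}
    clusters = {gid: detect_clusters(g) for gid, g in genomes.items()}
    conserved = conserved_clusters(list(genomes.values()), clusters)
    blocks_by_cms = {
        c: classify_blocks(build_synteny_blocks(genomes[c], genomes[m]))
        for m, c in PAIRS
    }
    map_clusters_to_blocks(conserved, blocks_by_cms)
    rows = []
    for cc in conserved:
        rows.append(dict(
            signature=cc.name,
            **{gid: f"{s}-{e}" for gid, (s, e) in cc.instances.items()},
            **{f"{gid}_context": v for gid, v in cc.block_context.items()},
        ))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "gene_clusters.tsv", sep="\t", index=False)
    print(f"{len(conserved)} conserved clusters:")
    print(df[["signature", "A_cms_context", "B_cms_context"]])
    ov = {gid: gene_overlaps(g) for gid, g in genomes.items()}
    print("\noverlapping gene pairs:", ov)


if __name__ == "__main__":
    main()
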
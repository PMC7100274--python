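"""Candidate CMS-associated genes: polymorphisms and copy numbers.

Pairs protein-coding homologs within each cultivar, calls codon-level
polymorphisms (Table-style events, substitutions classified as synonymous
or non-synonymous), tabulates gene copy numbers, and intersects the two
cultivars' polymorphic gene sets — the intersection is the candidate list.
"""

from pathlib import Path

import pandas as pd

from mitocompare.genes import call_polymorphisms, copy_numbers, intersect_candidates
from mitocompare.genome_io import attach_gff3, read_fasta

PAIRS = [("A_maint", "A_cms"), ("B_maint", "B_cms")]
IN = Path("results/genomes")
OUT = Path("results")


def load(gid):
    g = read_fasta(IN / f"{gid}.fasta")[0]
    g.id = gid
    return attach_gff3(g, IN / f"{gid}.gff3")


def main() -> None:
    genomes = {gid: load(gid) for pair in PAIRS for gid in pair}
    per_cultivar = {}
    rows = []
    for m_id, c_id in PAIRS:
        recs = call_polymorphisms(genomes[m_id], genomes[c_id], cultivar=m_id[0])
        per_cultivar[m_id[0]] = recs
        for r in recs:
            for e in r.events:
                rows.append(dict(cultivar=m_id[0], gene=r.gene,
                                 length_change=f"{r.length_a} -> {r.length_b}"
                                 if r.length_a != r.length_b else "*",
                                 event=e.format_table(), synonymy=e.synonymy))
    pd.DataFrame(rows).to_csv(OUT / "polymorphisms.tsv", sep="\t", index=False)
    cn = copy_numbers(list(genomes.values()))
    cn.to_csv(OUT / "copy_numbers.tsv", sep="\t")
    cands = intersect_candidates(list(per_cultivar.values()))
    poly_sets = {cv: sorted({r.gene for r in recs if r.polymorphic})
                 for cv, recs in per_cultivar.items()}
    print("polymorphic genes per cultivar:",
          {cv: len(v) for cv, v in poly_sets.items()}, poly_sets)
    print("candidate CMS-associated genes (intersection):", cands)
    print("\ncopy-number differences:")
    print(cn[cn.nunique(axis=1) > 1])
    Path(OUT / "candidate_genes.txt").write_text("\n".join(cands) + "\n")


if __name__ == "__main__":
    main()
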
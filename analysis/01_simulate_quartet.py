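"""Simulate the study system: two maintainer/CMS genome pairs + outgroup.

Generates the default synthetic quartet (two tobacco-like cultivars, each a
~430 kb maintainer mitochondrial genome and its CMS derivative sharing one
alien-cytoplasm haplotype, plus an outgroup reference), and writes FASTA +
GFF3 for every genome under results/genomes/ together with a truth summary.
Later analysis steps read these files — nothing downstream sees the truth.
"""

import json
from pathlib import Path

from mitocompare.genome_io import write_fasta, write_gff3
from mitocompare.simulate import SimConfig, Simulator

SEED = 1
OUT = Path("results/genomes")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = Simulator(SimConfig(seed=SEED))
    quartet = sim.quartet()
    summary = {}
    for gid, genome in quartet.genomes.items():
        write_fasta(genome, OUT / f"{gid}.fasta")
        write_gff3(genome, OUT / f"{gid}.gff3")
        summary[gid] = {"length": genome.length, "genes": len(genome.genes)}
    truth = quartet.truth
    summary["planted"] = {
        "expansion_bp": {c: truth.expansion(c) for c in ("A_cms", "B_cms")},
        "shared_specific_orfs": truth.config.n_specific_orfs,
        "region_lengths": list(truth.config.region_lengths),
        "conserved_clusters": len(truth.cluster_signatures),
    }
    (OUT / "simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {len(quartet.genomes)} genomes (seed {SEED}) to {OUT}/")
    for gid, s in summary.items():
        if gid != "planted":
            print(f"  {gid}: {s['length']:,} bp, {s['genes']} gene features")
    print("planted:", summary["planted"])


if __name__ == "__main__":
    main()
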
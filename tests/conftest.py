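import numpy as np
import pytest

from mitocompare.simulate import SimConfig, Simulator


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def quartet():
    """The default simulated study system (seed 1): two maintainer/CMS
    pairs sharing a CMS haplotype, plus an outgroup reference."""
    return Simulator(SimConfig(seed=1)).quartet()


@pytest.fixture(scope="session")
def pair_blocks(quartet):
    """Classified synteny blocks per cultivar, maintainer as genome A."""
    from mitocompare.synteny import build_synteny_blocks, classify_blocks

    out = {}
    for cv in ("A", "B"):
        m = quartet.genomes[f"{cv}_maint"]
        c = quartet.genomes[f"{cv}_cms"]
        out[cv] = classify_blocks(build_synteny_blocks(m, c, min_block=3000))
    return out


@pytest.fixture(scope="session")
def specific_orf_sets(quartet):
    from mitocompare.orfs import screen_specific_orfs

    return {
        f"{cv}_cms": screen_specific_orfs(
            quartet.genomes[f"{cv}_cms"], quartet.genomes[f"{cv}_maint"]
        )
        for cv in ("A", "B")
    }


@pytest.fixture(scope="session")
def polymorphisms(quartet):
    from mitocompare.genes import call_polymorphisms

    return {
        cv: call_polymorphisms(
            quartet.genomes[f"{cv}_maint"], quartet.genomes[f"{cv}_cms"], cv
        )
        for cv in ("A", "B")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
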
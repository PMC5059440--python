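import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from adaptscan.pipeline import run_pipeline
from adaptscan.reference import CrisprLocus, ReferenceSet, Replicon, SeedSite, seed_site_pam
from adaptscan.simulate import SimConfig, default_reference, emit_amplicons, simulate_population


@pytest.fixture(scope="session")
def refset():
    """Default synthetic reference: circular plasmid with a TG-PAM priming site."""
    return default_reference(seed=0)


@pytest.fixture(scope="session")
def sim_10k(refset):
    """One 10,000-cell priming simulation with documented defaults, run once."""
    config = SimConfig(n_cells=10_000, seed=11)
    truth = simulate_population(refset, config)
    reads = emit_amplicons(truth, refset, config)
    result = run_pipeline(reads, refset)
    return config, truth, reads, result


@pytest.fixture()
def tiny_refset():
    """Hand-built two-replicon reference for deterministic unit tests."""
    rng = np.random.default_rng(42)
    plasmid_seq = "".join(rng.choice(list("ACGT"), size=300))
    chrom_seq = "".join(rng.choice(list("ACGT"), size=400))
    plasmid = Replicon("p1", plasmid_seq, "circular", "plasmid")
    chrom = Replicon("c1", chrom_seq, "linear", "chromosome")
    locus = CrisprLocus(
        id="CRISPR1",
        repeat_seq="GTTCACTGCCGTGTAGGCAGCTAAGAAA",
        leader_barcode="ACGTCA",
        preexisting_spacers=("A" * 16 + "C" * 16,),
        incorporation_weight=1.0,
        leader_tail="TTGACAGCTAGCTCA",
        primer3_tag="ACCAGGTTACCA",
    )
    return ReferenceSet(
        replicons={"p1": plasmid, "c1": chrom},
        loci={"CRISPR1": locus},
        seed_sites=[],
    )
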
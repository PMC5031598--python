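import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gcxscan import genome_io
from gcxscan.simulate import SimulationConfig, simulate_dataset, write_outputs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, alphabet="ACGT", n_prob=0.0):
    """Random nucleotide string, optionally salted with Ns."""
    bases = rng.choice(list(alphabet), size=length)
    if n_prob:
        bases[rng.random(length) < n_prob] = "N"
    return "".join(bases)


MINUS_STRAND_CONTIG = "AAACCCGGGTTTAAACCCGGGTTTA"  # 25 nt toy

MINUS_STRAND_GFF = """##gff-version 3
c1\ttoy\tgene\t1\t19\t.\t-\t.\tID=g1
c1\ttoy\tmRNA\t1\t19\t.\t-\t.\tID=g1.t1;Parent=g1
c1\ttoy\tCDS\t11\t19\t.\t-\t0\tParent=g1.t1
c1\ttoy\tCDS\t1\t6\t.\t-\t0\tParent=g1.t1
"""

# spliced by hand: revcomp(seq[10:19]) + revcomp(seq[0:6])
MINUS_STRAND_CODING = "CGGGTTTAA" + "GGGTTT"


@pytest.fixture
def minus_strand_toy(tmp_path):
    fasta = tmp_path / "toy.fasta"
    fasta.write_text(f">c1\n{MINUS_STRAND_CONTIG}\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(MINUS_STRAND_GFF)
    return fasta, gff


@pytest.fixture(scope="session")
def small_simulation(tmp_path_factory):
    """A 120-gene simulated dataset, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("sim")
    sim = simulate_dataset(SimulationConfig(n_genes=120), seed=7, outdir=outdir)
    return sim, outdir


def make_two_exon_gene(utr5=10, cds1=30, intron=20, cds2=29, utr3=10, contig_len=None):
    """Plus-strand two-exon gene model on a synthetic layout, for localization tests."""
    s0 = 0
    u5 = (s0, s0 + utr5)
    c1 = (u5[1], u5[1] + cds1)
    c2 = (c1[1] + intron, c1[1] + intron + cds2)
    u3 = (c2[1], c2[1] + utr3)
    phase2 = (3 - (cds1 % 3)) % 3
    gene = genome_io.GeneModel(
        gene_id="gX",
        contig_id="c1",
        strand="+",
        cds_segments=[
            genome_io.CdsSegment("c1", *c1, "+", 0),
            genome_io.CdsSegment("c1", *c2, "+", phase2),
        ],
        exon_segments=[(u5[0], c1[1]), (c2[0], u3[1])],
        utr5=[u5],
        utr3=[u3],
    )
    return gene
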
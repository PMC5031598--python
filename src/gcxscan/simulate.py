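"""Synthetic genomes with known truth for end-to-end pipeline testing.

The generator emits a FASTA + GFF3 pair plus truth tables that state, for
every gene, its GC_x class, every planted motif instance (offset, frame,
sequence) and its expression label.  The stated world mirrors the
genome-scale observations the analysis targets, scaled down:

- gene classes high-GC1 / high-GC2 / high-GC3 / low in proportions
  0.092 / 0.016 / 0.144 / remainder (the genome-wide class fractions);
- a high class puts GC probability 0.90 at its designated codon
  position; low-class genes sit at (0.52, 0.45, 0.52), matching the
  low-mode peaks of the bimodal GC_x densities;
- introns and intergenic spacers are GC-poorer than exons;
- motif instances are sampled from the consensus PWM, planted
  codon-aligned into CDS runs with a configurable frame distribution and
  per-gene count distribution (geometric, truncated at 16), with genes
  chosen at 5:1 odds toward high-GC_x classes;
- expression labels are drawn with configurable odds linking up/down
  status to motif presence (default: up-regulation biased against motif
  genes).

Codons are sampled per-position independently (not from a codon-usage
table): the downstream analysis consumes only positional GC, and
independence makes the truth values analytic.  Stop codons are resampled
away inside CDS bodies; one stop is appended per gene (T, A, then G or A
drawn at the gene's GC3 probability so degenerate GC3=1 configs stay
exact).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .enrichment import ExpressionLabelSet
from .genome_io import CdsSegment, GeneModel, reverse_complement
from .motif_scan import DEFAULT_CONSENSUS, MotifModel, consensus_to_pwm

log = logging.getLogger(__name__)

_FRAME_TOTAL = 868 + 389 + 1094  # observed genome-scale frame split


@dataclass
class SimulationConfig:
    """Stated world of one simulation; every field has a documented default."""

    n_genes: int = 500
    class_probs: dict = field(
        default_factory=lambda: {"high1": 0.092, "high2": 0.016, "high3": 0.144}
    )
    high_gc: float = 0.90
    base_gc: tuple = (0.52, 0.45, 0.52)  # low-class / non-designated codon positions
    intron_gc: float = 0.40
    utr_gc: float = 0.45
    intergenic_gc: float = 0.35
    n_codons_range: tuple = (100, 300)
    n_exons_range: tuple = (1, 4)
    intron_len_range: tuple = (60, 200)
    utr5_len_range: tuple = (20, 100)
    utr3_len_range: tuple = (20, 100)
    flank_len_range: tuple = (100, 300)
    # motif planting
    consensus: str = DEFAULT_CONSENSUS
    stringency: float = 0.80
    motif_gene_fraction: float = 0.10
    motif_enrichment_odds: float = 5.0
    motif_count_p: float = 0.25  # geometric success prob; mean ~= 1/p
    motif_count_max: int = 16
    frame_probs: tuple = (868 / _FRAME_TOTAL, 389 / _FRAME_TOTAL, 1094 / _FRAME_TOTAL)
    consensus_max_instances: bool = False
    # expression labels
    up_fraction: dict = field(
        default_factory=lambda: {"seedling": 3236 / 39656, "anther": 189 / 39656}
    )
    down_fraction: dict = field(
        default_factory=lambda: {"seedling": 4140 / 39656, "anther": 232 / 39656}
    )
    motif_up_odds: float = 0.25
    motif_down_odds: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        total_high = sum(self.class_probs.values())
        if total_high > 1 + 1e-9:
            raise ValueError("class probabilities exceed 1")
        probs = [self.high_gc, *self.base_gc, self.intron_gc, self.utr_gc, self.intergenic_gc]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all GC probabilities must lie in [0, 1]")
        if 3 * (self.n_codons_range[0] + 1) < 19:
            raise ValueError("motif longer than shortest possible CDS")
        if abs(sum(self.frame_probs) - 1) > 1e-9:
            raise ValueError("frame_probs must sum to 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in (
            "base_gc",
            "n_codons_range",
            "n_exons_range",
            "intron_len_range",
            "utr5_len_range",
            "utr3_len_range",
            "flank_len_range",
            "frame_probs",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PlantedMotif:
    gene_id: str
    cds_offset: int
    codon_frame: int
    genomic_start: int
    strand: str
    sequence: str  # coding orientation


@dataclass
class Simulation:
    """In-memory simulated dataset: contigs, gene models and truth tables."""

    config: SimulationConfig
    contigs: dict[str, str]
    genes: list[GeneModel]
    true_class: dict[str, str]
    planted: list[PlantedMotif] = field(default_factory=list)
    labels: Optional[ExpressionLabelSet] = None

    @property
    def truth(self) -> pd.DataFrame:
        counts: dict[str, int] = {}
        for m in self.planted:
            counts[m.gene_id] = counts.get(m.gene_id, 0) + 1
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "contig": g.contig_id,
                    "strand": g.strand,
                    "true_class": self.true_class[g.gene_id],
                    "n_motifs": counts.get(g.gene_id, 0),
                    "has_motif": counts.get(g.gene_id, 0) > 0,
                }
            )
        return pd.DataFrame(rows)

    def motif_truth(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.planted])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    if length == 0:
        return ""
    is_gc = rng.random(length) < gc
    strong = rng.integers(0, 2, length)  # G vs C / A vs T split evenly
    out = np.where(is_gc, np.where(strong == 0, ord("G"), ord("C")),
                   np.where(strong == 0, ord("A"), ord("T")))
    return out.astype(np.uint8).tobytes().decode("ascii")


_STOPS = ("TAA", "TAG", "TGA")


def _sample_coding(rng: np.random.Generator, n_codons: int, p: tuple[float, float, float]) -> str:
    """Coding sequence of n_codons body codons plus one appended stop."""
    codons: list[str] = []
    for _ in range(n_codons):
        while True:
            codon = "".join(
                ("G" if rng.integers(0, 2) == 0 else "C")
                if rng.random() < p[k]
                else ("A" if rng.integers(0, 2) == 0 else "T")
                for k in range(3)
            )
            if codon not in _STOPS:
                break
        codons.append(codon)
    stop = "TA" + ("G" if rng.random() < p[2] else "A")
    return "".join(codons) + stop


def _class_gc_probs(cls: str, config: SimulationConfig) -> tuple[float, float, float]:
    p = list(config.base_gc)
    if cls.startswith("high"):
        p[int(cls[-1]) - 1] = config.high_gc
    return tuple(p)


def _split_lengths(rng: np.random.Generator, total: int, n_parts: int, min_len: int) -> list[int]:
    if n_parts == 1 or total < n_parts * min_len:
        return [total]
    extra = rng.multinomial(total - n_parts * min_len, np.full(n_parts, 1 / n_parts))
    return [min_len + int(e) for e in extra]


def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> Simulation:
    """Draw a genome of one-gene contigs per the configured stated world.

    Deterministic under a fixed generator state; the same seed yields
    byte-identical FASTA/GFF3 output.
    """
    class_names = list(config.class_probs) + ["low"]
    probs = list(config.class_probs.values())
    probs.append(max(0.0, 1.0 - sum(probs)))
    probs = np.asarray(probs) / np.sum(probs)

    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    true_class: dict[str, str] = {}
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        gene_id = f"gene{i:0{width}d}"
        contig_id = f"ctg{i:0{width}d}"
        cls = class_names[rng.choice(len(class_names), p=probs)]
        p_gc = _class_gc_probs(cls, config)
        n_codons = int(rng.integers(config.n_codons_range[0], config.n_codons_range[1] + 1))
        coding = _sample_coding(rng, n_codons, p_gc)
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        seg_lengths = _split_lengths(rng, len(coding), n_exons, min_len=30)
        introns = [
            _random_seq(rng, int(rng.integers(*config.intron_len_range)), config.intron_gc)
            for _ in range(len(seg_lengths) - 1)
        ]
        utr5 = _random_seq(rng, int(rng.integers(*config.utr5_len_range)), config.utr_gc)
        utr3 = _random_seq(rng, int(rng.integers(*config.utr3_len_range)), config.utr_gc)
        flank5 = _random_seq(rng, int(rng.integers(*config.flank_len_range)), config.intergenic_gc)
        flank3 = _random_seq(rng, int(rng.integers(*config.flank_len_range)), config.intergenic_gc)
        strand = "+" if rng.integers(0, 2) == 0 else "-"

        # forward (transcription-orientation) layout with recorded intervals
        parts = [flank5, utr5]
        pos = len(flank5)
        utr5_iv = (pos, pos + len(utr5))
        pos += len(utr5)
        cds_fwd: list[tuple[int, int]] = []
        consumed = 0
        for j, seg_len in enumerate(seg_lengths):
            parts.append(coding[consumed : consumed + seg_len])
            cds_fwd.append((pos, pos + seg_len))
            pos += seg_len
            consumed += seg_len
            if j < len(introns):
                parts.append(introns[j])
                pos += len(introns[j])
        utr3_iv = (pos, pos + len(utr3))
        parts.append(utr3)
        pos += len(utr3)
        parts.append(flank3)
        forward = "".join(parts)
        L = len(forward)

        if strand == "+":
            contig = forward
            mirror = lambda iv: iv  # noqa: E731
        else:
            contig = reverse_complement(forward)
            mirror = lambda iv: (L - iv[1], L - iv[0])  # noqa: E731

        # phases forced by cumulative segment lengths, first segment phase 0
        phases = []
        cum = 0
        for seg_len in seg_lengths:
            phases.append((3 - (cum % 3)) % 3)
            cum += seg_len
        cds_segments = [
            CdsSegment(contig_id, *mirror(iv), strand, phase)
            for iv, phase in zip(cds_fwd, phases)
        ]
        utr5_g = [mirror(utr5_iv)] if utr5 else []
        utr3_g = [mirror(utr3_iv)] if utr3 else []
        # exons: UTR5 + first CDS piece, middle CDS pieces, last CDS piece + UTR3
        exon_fwd = []
        for j, iv in enumerate(cds_fwd):
            s, e = iv
            if j == 0 and utr5:
                s = utr5_iv[0]
            if j == len(cds_fwd) - 1 and utr3:
                e = utr3_iv[1]
            exon_fwd.append((s, e))
        exons = sorted(mirror(iv) for iv in exon_fwd)

        gene = GeneModel(
            gene_id=gene_id,
            contig_id=contig_id,
            strand=strand,
            cds_segments=cds_segments,
            exon_segments=exons,
            utr5=utr5_g,
            utr3=utr3_g,
            transcript_id=f"{gene_id}_t1",
            coding_sequence=coding,
            coding_phase_offset=0,
        )
        contigs[contig_id] = contig
        genes.append(gene)
        true_class[gene_id] = cls
    return Simulation(config=config, contigs=contigs, genes=genes, true_class=true_class)


def plant_motifs(
    sim: Simulation, rng: np.random.Generator, model: Optional[MotifModel] = None
) -> Simulation:
    """Write motif instances into selected genes' CDS, updating truth in place.

    Target genes are drawn without replacement with weights of
    ``motif_enrichment_odds`` for high-GC_x genes versus 1 for low genes;
    instances are sampled from the PWM (or set to the consensus-max
    19-mer), placed codon-aligned at a frame drawn from ``frame_probs``,
    non-overlapping within a gene, entirely inside one CDS segment.  A
    gene with no feasible site is skipped with a log entry.
    """
    config = sim.config
    if model is None:
        model = consensus_to_pwm(config.consensus, stringency=config.stringency)
    L = len(model)
    n_target = int(round(config.motif_gene_fraction * config.n_genes))
    if n_target == 0:
        return sim
    weights = np.array(
        [
            config.motif_enrichment_odds if sim.true_class[g.gene_id] != "low" else 1.0
            for g in sim.genes
        ]
    )
    weights = weights / weights.sum()
    chosen = rng.choice(len(sim.genes), size=n_target, replace=False, p=weights)
    frame_probs = np.asarray(config.frame_probs)

    for gi in sorted(chosen):
        gene = sim.genes[gi]
        n_instances = min(int(rng.geometric(config.motif_count_p)), config.motif_count_max)
        # coding-space spans of each CDS segment, transcription order
        spans = []
        cum = 0
        for seg in gene.cds_segments:
            spans.append((cum, cum + len(seg)))
            cum += len(seg)
        used: list[tuple[int, int]] = []
        planted_here = 0
        for _ in range(n_instances):
            placed = False
            for _attempt in range(60):
                frame = int(rng.choice(3, p=frame_probs)) + 1
                cs, ce = spans[int(rng.choice(len(spans)))]
                lo = cs + ((frame - 1 - cs) % 3)
                if lo + L > ce:
                    continue
                n_slots = (ce - L - lo) // 3 + 1
                o = lo + 3 * int(rng.integers(0, n_slots))
                if any(o < ue and u < o + L for u, ue in used):
                    continue
                instance = (
                    model.consensus_max_sequence()
                    if config.consensus_max_instances
                    else _sample_instance(rng, model)
                )
                _write_instance(sim, gene, o, instance)
                used.append((o, o + L))
                g_first = gene.genomic_of_cds_offset(o)
                g_last = gene.genomic_of_cds_offset(o + L - 1)
                sim.planted.append(
                    PlantedMotif(
                        gene_id=gene.gene_id,
                        cds_offset=o,
                        codon_frame=frame,
                        genomic_start=min(g_first, g_last),
                        strand=gene.strand,
                        sequence=instance,
                    )
                )
                planted_here += 1
                placed = True
                break
            if not placed:
                log.info("gene %s: no feasible motif site; instance skipped", gene.gene_id)
    return sim


def _sample_instance(rng: np.random.Generator, model: MotifModel) -> str:
    bases = "ACGT"
    seq = "".join(bases[rng.choice(4, p=model.pwm[i])] for i in range(len(model)))
    # uniform-within-code PWM: every allowed base attains the positional max,
    # so sampled instances score max_score by construction
    return seq


def _write_instance(sim: Simulation, gene: GeneModel, offset: int, instance: str) -> None:
    L = len(instance)
    coding = gene.coding_sequence
    gene.coding_sequence = coding[:offset] + instance + coding[offset + L :]
    g_first = gene.genomic_of_cds_offset(offset)
    g_last = gene.genomic_of_cds_offset(offset + L - 1)
    contig = sim.contigs[gene.contig_id]
    if gene.strand == "+":
        s = g_first
        sim.contigs[gene.contig_id] = contig[:s] + instance + contig[s + L :]
    else:
        s = g_last
        sim.contigs[gene.contig_id] = contig[:s] + reverse_complement(instance) + contig[s + L :]


def simulate_expression_labels(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> ExpressionLabelSet:
    """Draw up/down/none expression labels per comparison tissue.

    ``truth`` needs columns gene_id and has_motif.  Motif presence scales
    the up (resp. down) probability by the configured odds; a gene is
    never both up and down in one comparison.
    """
    frames = []
    gene_ids = truth["gene_id"].to_numpy()
    has_motif = truth["has_motif"].to_numpy()
    for comparison in sorted(set(config.up_fraction) | set(config.down_fraction)):
        base_up = config.up_fraction.get(comparison, 0.0)
        base_down = config.down_fraction.get(comparison, 0.0)
        p_up = np.where(has_motif, min(1.0, base_up * config.motif_up_odds), base_up)
        p_down = np.where(has_motif, min(1.0, base_down * config.motif_down_odds), base_down)
        u = rng.random(len(gene_ids))
        up_mask = u < p_up
        down_mask = ~up_mask & (u < p_up + p_down)
        for direction, mask in (("up", up_mask), ("down", down_mask)):
            if mask.any():
                frames.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids[mask],
                            "direction": direction,
                            "comparison": comparison,
                        }
                    )
                )
    if frames:
        labels = pd.concat(frames, ignore_index=True)
    else:
        labels = pd.DataFrame(columns=["gene_id", "direction", "comparison"])
    return ExpressionLabelSet(labels, universe=set(gene_ids))


# ---------------------------------------------------------------------------
# output

def write_fasta(contigs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span_s, span_e = g.span
            tid = g.transcript_id or f"{g.gene_id}_t1"
            fh.write(_gff_line(g.contig_id, "gene", span_s, span_e, g.strand, ".", f"ID={g.gene_id}"))
            fh.write(
                _gff_line(g.contig_id, "mRNA", span_s, span_e, g.strand, ".", f"ID={tid};Parent={g.gene_id}")
            )
            for s, e in g.exon_segments:
                fh.write(_gff_line(g.contig_id, "exon", s, e, g.strand, ".", f"Parent={tid}"))
            for s, e in g.utr5:
                fh.write(_gff_line(g.contig_id, "five_prime_UTR", s, e, g.strand, ".", f"Parent={tid}"))
            for s, e in g.utr3:
                fh.write(_gff_line(g.contig_id, "three_prime_UTR", s, e, g.strand, ".", f"Parent={tid}"))
            for seg in sorted(g.cds_segments, key=lambda s: s.start):
                fh.write(
                    _gff_line(
                        g.contig_id, "CDS", seg.start, seg.end, g.strand, str(seg.phase), f"Parent={tid}"
                    )
                )


def _gff_line(contig, ftype, start0, end0, strand, phase, attrs) -> str:
    return f"{contig}\tgcxscan_sim\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t{phase}\t{attrs}\n"


def write_outputs(sim: Simulation, outdir) -> dict[str, Path]:
    """Emit FASTA, GFF3, truth TSVs, label TSV and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "annotation.gff3",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_motifs": outdir / "truth_motifs.tsv",
        "config": outdir / "config.yaml",
    }
    write_fasta(sim.contigs, paths["fasta"])
    write_gff3(sim.genes, paths["gff3"])
    sim.truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    sim.motif_truth().to_csv(paths["truth_motifs"], sep="\t", index=False)
    sim.config.to_yaml(paths["config"])
    if sim.labels is not None:
        paths["labels"] = outdir / "expression_labels.tsv"
        sim.labels.labels.to_csv(paths["labels"], sep="\t", index=False)
    return paths


def simulate_dataset(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    outdir=None,
) -> Simulation:
    """One-call simulation: genome + planted motifs + expression labels."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    sim = simulate_genome(config, rng)
    plant_motifs(sim, rng)
    sim.labels = simulate_expression_labels(sim.truth, config, rng)
    if outdir is not None:
        write_outputs(sim, outdir)
    return sim
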
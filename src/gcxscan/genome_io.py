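"""Genome and annotation ingestion.

Reads a genome FASTA and a GFF3 gene annotation, reduces each locus to a
single representative transcript, and assembles the phase-aware spliced
coding sequence that every downstream GC and motif computation operates on.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open on the forward strand of
the contig.  GFF3 input (1-based closed) is converted on read; anything
emitted as GFF3 is converted back, and anything emitted as BED stays
0-based half-open.

CDS *phase* follows the GFF3 definition: the number of bases that must be
removed from the start of the segment (in transcription order) to reach
the first base of a complete codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

_RC_TABLE = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet."""
    return seq.translate(_RC_TABLE)[::-1]


class RegionClass(Enum):
    """Mutually exclusive region class of a genomic position w.r.t. one gene model."""

    CDS = "CDS"
    INTRON = "INTRON"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: an identifier plus an uppercase nucleotide string."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} contains non-IUPAC characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsSegment:
    """A single CDS interval, 0-based half-open, with its GFF3 phase."""

    contig_id: str
    start: int
    end: int
    strand: str
    phase: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"CDS segment requires start < end, got [{self.start}, {self.end})")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One gene reduced to a representative transcript.

    ``cds_segments`` is in transcription order (reversed genomic order on
    the minus strand).  ``coding_sequence`` and ``coding_phase_offset``
    are filled by :func:`assemble_coding_sequence`.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_segments: list[CdsSegment] = field(default_factory=list)
    exon_segments: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    transcript_id: Optional[str] = None
    coding_sequence: Optional[str] = None
    coding_phase_offset: int = 0

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) covered by the representative transcript."""
        intervals = list(self.exon_segments) + [(s.start, s.end) for s in self.cds_segments]
        if not intervals:
            raise ValueError(f"gene {self.gene_id} has no intervals")
        return min(s for s, _ in intervals), max(e for _, e in intervals)

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    def cds_offset_of(self, pos: int) -> Optional[int]:
        """Spliced coding-sequence offset of genomic position ``pos``.

        Returns None when the position is not inside any CDS segment.
        """
        cum = 0
        for seg in self.cds_segments:
            if seg.start <= pos < seg.end:
                if self.strand == "+":
                    return cum + (pos - seg.start)
                return cum + (seg.end - 1 - pos)
            cum += len(seg)
        return None

    def genomic_of_cds_offset(self, offset: int) -> Optional[int]:
        """Inverse of :meth:`cds_offset_of`."""
        cum = 0
        for seg in self.cds_segments:
            if cum <= offset < cum + len(seg):
                if self.strand == "+":
                    return seg.start + (offset - cum)
                return seg.end - 1 - (offset - cum)
            cum += len(seg)
        return None

    def classify_position(self, pos: int) -> RegionClass:
        start, end = self.span
        if not (start <= pos < end):
            return RegionClass.INTERGENIC
        for seg in self.cds_segments:
            if seg.start <= pos < seg.end:
                return RegionClass.CDS
        for s, e in self.utr5:
            if s <= pos < e:
                return RegionClass.UTR5
        for s, e in self.utr3:
            if s <= pos < e:
                return RegionClass.UTR3
        return RegionClass.INTRON


# ---------------------------------------------------------------------------
# coordinate conversion helpers (round-trip tested)

def gff3_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    return start_1based - 1, end_1based


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-)FASTA into ``{contig_id: GenomeSequence}`` in file order.

    Sequences are uppercased; soft-masked (lowercase) bases are preserved
    as their uppercase nucleotide.  Duplicate contig ids are an error.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        records[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# GFF3

def _propagate_phases(lengths: list[int], phases: list[Optional[int]], gene_id: str) -> list[int]:
    """Fill missing CDS phases from segment lengths (transcription order).

    A missing first phase is assumed 0.  Explicit phases are trusted and
    propagation restarts from them.
    """
    out: list[int] = []
    expected = 0
    for i, (length, phase) in enumerate(zip(lengths, phases)):
        if phase is None:
            phase = expected
        out.append(phase)
        expected = (3 - ((length - phase) % 3)) % 3
    return out


def _merge_overlapping(segments: list[CdsSegment], strand: str) -> list[CdsSegment]:
    """Merge overlapping CDS intervals within one transcript.

    Valid GFF3 should not need this, but overlaps are tolerated; the merged
    segment keeps the phase of its first piece in transcription order.
    """
    if len(segments) <= 1:
        return list(segments)
    by_start = sorted(segments, key=lambda s: s.start)
    merged: list[list] = [[by_start[0].start, by_start[0].end, [by_start[0]]]]
    for seg in by_start[1:]:
        last = merged[-1]
        if seg.start < last[1]:  # strict overlap only
            last[1] = max(last[1], seg.end)
            last[2].append(seg)
        else:
            merged.append([seg.start, seg.end, [seg]])
    out = []
    for start, end, pieces in merged:
        # first piece in transcription order donates the phase
        first = min(pieces, key=lambda s: s.start) if strand == "+" else max(pieces, key=lambda s: s.start)
        out.append(CdsSegment(pieces[0].contig_id, start, end, strand, first.phase))
    if strand == "-":
        out.sort(key=lambda s: -s.start)
    else:
        out.sort(key=lambda s: s.start)
    return out


def _feature_interval(f: gffutils.Feature) -> tuple[int, int]:
    return gff3_to_internal(f.start, f.end)


def _collect_cds(db: gffutils.FeatureDB, parent: gffutils.Feature, gene_id: str) -> list[CdsSegment]:
    feats = list(db.children(parent, featuretype="CDS", order_by="start"))
    if not feats:
        return []
    strand = feats[0].strand
    if strand == "-":
        feats = feats[::-1]  # transcription order
    lengths, phases = [], []
    for f in feats:
        s, e = _feature_interval(f)
        lengths.append(e - s)
        phases.append(int(f.frame) if f.frame in ("0", "1", "2") else None)
    phases = _propagate_phases(lengths, phases, gene_id)
    segments = []
    for f, phase in zip(feats, phases):
        s, e = _feature_interval(f)
        segments.append(CdsSegment(f.seqid, s, e, strand, phase))
    return _merge_overlapping(segments, strand)


def _derive_utrs(
    exons: list[tuple[int, int]], cds: list[CdsSegment], strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exonic sequence outside the CDS span, split 5'/3' on the coding strand."""
    if not cds or not exons:
        return [], []
    cds_min = min(s.start for s in cds)
    cds_max = max(s.end for s in cds)
    upstream, downstream = [], []
    for s, e in exons:
        if s < cds_min:
            upstream.append((s, min(e, cds_min)))
        if e > cds_max:
            downstream.append((max(s, cds_max), e))
    if strand == "+":
        return upstream, downstream
    return downstream, upstream


def read_annotation(path: str | Path, genome: Optional[dict[str, GenomeSequence]] = None) -> list[GeneModel]:
    """Read GFF3 into one :class:`GeneModel` per gene.

    When a gene carries several mRNAs, the representative transcript is the
    one with the longest total CDS (ties broken by lexicographically
    smallest transcript id).  Genes without any CDS are retained but
    flagged non-coding (``is_coding`` False).  When ``genome`` is given,
    coding sequences are assembled immediately.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        transcripts = list(db.children(gene, level=1, featuretype=("mRNA", "transcript")))
        candidates: list[tuple[int, str, gffutils.Feature]] = []
        if transcripts:
            for t in transcripts:
                tid = t.attributes.get("ID", [t.id])[0]
                total = sum(f.end - f.start + 1 for f in db.children(t, featuretype="CDS"))
                candidates.append((total, tid, t))
        else:
            candidates.append(
                (sum(f.end - f.start + 1 for f in db.children(gene, featuretype="CDS")), gene_id, gene)
            )
        candidates.sort(key=lambda c: (-c[0], c[1]))
        _, tid, rep = candidates[0]

        cds = _collect_cds(db, rep, gene_id)
        exons = [_feature_interval(f) for f in db.children(rep, featuretype="exon", order_by="start")]
        utr5 = [
            _feature_interval(f)
            for f in db.children(rep, featuretype=("five_prime_UTR", "5UTR"), order_by="start")
        ]
        utr3 = [
            _feature_interval(f)
            for f in db.children(rep, featuretype=("three_prime_UTR", "3UTR"), order_by="start")
        ]
        if not utr5 and not utr3:
            utr5, utr3 = _derive_utrs(exons, cds, gene.strand)
        if not exons:
            exons = sorted(
                [(s.start, s.end) for s in cds] + utr5 + utr3
            )
        model = GeneModel(
            gene_id=gene_id,
            contig_id=gene.seqid,
            strand=gene.strand,
            cds_segments=cds,
            exon_segments=exons,
            utr5=utr5,
            utr3=utr3,
            transcript_id=tid if cds or transcripts else None,
        )
        if not model.is_coding:
            warnings.warn(f"gene {gene_id} has no CDS; retained as non-coding", stacklevel=2)
        elif genome is not None:
            assemble_coding_sequence(model, genome[model.contig_id])
        genes.append(model)
    return genes


def assemble_coding_sequence(gene: GeneModel, genome: GenomeSequence) -> tuple[str, int]:
    """Splice the gene's CDS segments into its coding sequence.

    Segments are concatenated in transcription order, reverse-complemented
    on the minus strand.  The returned phase offset is the phase of the
    first segment: that many leading bases belong to no complete codon and
    are dropped before codon framing downstream.
    """
    if not gene.cds_segments:
        raise ValueError(f"gene {gene.gene_id} has no CDS segments")
    parts = []
    for seg in gene.cds_segments:
        if seg.end > len(genome.sequence) or seg.start < 0:
            raise ValueError(
                f"gene {gene.gene_id}: CDS [{seg.start},{seg.end}) exceeds contig "
                f"{genome.contig_id!r} bounds (len {len(genome.sequence)})"
            )
        chunk = genome.sequence[seg.start:seg.end]
        parts.append(reverse_complement(chunk) if gene.strand == "-" else chunk)
    seq = "".join(parts)
    offset = gene.cds_segments[0].phase
    gene.coding_sequence = seq
    gene.coding_phase_offset = offset
    return seq, offset


def classify_position(gene: GeneModel, pos: int) -> RegionClass:
    """Region class of a genomic position relative to one gene model."""
    return gene.classify_position(pos)


def gene_model_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Normalized per-gene summary (the gene-model TSV)."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "contig": g.contig_id,
                "strand": g.strand,
                "n_cds": len(g.cds_segments),
                "cds_len": g.cds_length,
                "phase_offset": g.coding_phase_offset if g.is_coding else pd.NA,
                "is_coding": g.is_coding,
            }
        )
    return pd.DataFrame(rows)
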
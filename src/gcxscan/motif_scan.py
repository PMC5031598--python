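"""Degenerate-consensus PWM scanning for the DSB-hotspot motif.

The 19-mer consensus GVSGRSGNSGRSGVSGRSG (near-invariant G every third
base) is expanded into a position weight matrix with the probability mass
of each position divided uniformly over the IUPAC-allowed bases, and
sequences are scanned with a log-odds score against a background
distribution.  A window is a hit when its score reaches a fractional
stringency (default 80%) of the maximum attainable score.

The PWM learned from the original ~900 hotspot regions is not published;
this uniform-within-code reconstruction is a documented stand-in that
preserves the motif's information structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .enrichment import ContingencyResult, gof_chisq
from .genome_io import GeneModel, RegionClass, reverse_complement

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_CONSENSUS = "GVSGRSGNSGRSGVSGRSG"

_BASES = "ACGT"
# byte lookup: A,C,G,T -> 0..3, anything else (N, ambiguity) -> 4
_BASE_LUT = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MotifModel:
    """Consensus-derived PWM with log-odds scores and threshold policy.

    ``score_matrix`` has 5 columns: A, C, G, T and a neutral N column
    (score 0, the log-odds of a background-distributed base), so windows
    containing N are scored rather than skipped.
    """

    consensus: str
    background: np.ndarray  # (4,)
    pwm: np.ndarray  # (L, 4) probabilities
    score_matrix: np.ndarray  # (L, 5) log2 odds
    max_score: float
    min_score: float
    stringency: float = 0.80
    threshold_anchor: str = "max"  # 'max' or 'minmax'

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def threshold(self) -> float:
        if self.threshold_anchor == "max":
            return self.stringency * self.max_score
        return self.min_score + self.stringency * (self.max_score - self.min_score)

    def consensus_max_sequence(self) -> str:
        """A sequence attaining max_score: G where allowed, else the first allowed base."""
        return "".join(
            "G" if "G" in IUPAC_CODES[c] else IUPAC_CODES[c][0] for c in self.consensus
        )


def consensus_to_pwm(
    consensus: str = DEFAULT_CONSENSUS,
    background: Optional[Iterable[float]] = None,
    stringency: float = 0.80,
    epsilon: float = 1e-3,
    threshold_anchor: str = "max",
) -> MotifModel:
    """Expand an IUPAC consensus into a scoring model.

    Each position's probability is 1/|allowed| for allowed bases and 0
    otherwise; log-odds use a pseudo-probability ``epsilon`` for
    disallowed bases so a mismatch is penalized but finite.
    """
    if not 0 < stringency <= 1:
        raise ValueError(f"stringency must be in (0, 1], got {stringency}")
    if threshold_anchor not in ("max", "minmax"):
        raise ValueError(f"threshold_anchor must be 'max' or 'minmax', got {threshold_anchor!r}")
    bg = np.full(4, 0.25) if background is None else np.asarray(list(background), dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    consensus = consensus.upper()
    L = len(consensus)
    pwm = np.zeros((L, 4))
    for i, code in enumerate(consensus):
        allowed = IUPAC_CODES.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r} at consensus position {i + 1}")
        for b in allowed:
            pwm[i, _BASES.index(b)] = 1.0 / len(allowed)
    scores = np.log2(np.maximum(pwm, epsilon) / bg)
    score_matrix = np.column_stack([scores, np.zeros(L)])  # N column neutral
    return MotifModel(
        consensus=consensus,
        background=bg,
        pwm=pwm,
        score_matrix=score_matrix,
        max_score=float(scores.max(axis=1).sum()),
        min_score=float(scores.min(axis=1).sum()),
        stringency=stringency,
        threshold_anchor=threshold_anchor,
    )


@dataclass
class MotifHit:
    """One motif occurrence, genomic coordinates on the forward strand.

    ``sequence`` is the motif-aligned 19-mer (reverse-complemented window
    for minus-strand hits).  Gene-relative fields are filled by
    :func:`localize_hits`; ``coding_sequence`` is the hit's footprint read
    in the host gene's coding orientation.
    """

    contig_id: str
    start: int
    strand: str
    score_fraction: float
    sequence: str
    gene_id: Optional[str] = None
    region: Optional[RegionClass] = None
    cds_offset: Optional[int] = None
    codon_frame: Optional[int] = None
    coding_sequence: Optional[str] = None
    flags: tuple[str, ...] = ()


def _scan_one_strand(seq: str, model: MotifModel) -> list[tuple[int, float]]:
    L = len(model)
    if len(seq) < L:
        return []
    idx = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = model.score_matrix[np.arange(L), windows].sum(axis=1)
    keep = np.flatnonzero(scores >= model.threshold)
    return [(int(i), float(scores[i])) for i in keep]


def scan(
    seq: str, model: MotifModel, both_strands: bool = True, contig_id: str = "seq"
) -> list[MotifHit]:
    """All windows scoring at or above the stringency threshold.

    Overlapping hits are all retained.  With ``both_strands`` the reverse
    complement is scanned too; coordinates are always reported on the
    forward strand and ``sequence`` holds the motif-aligned window.
    Sequences shorter than the motif yield an empty result.
    """
    seq = seq.upper()
    L = len(model)
    hits = [
        MotifHit(contig_id, i, "+", s / model.max_score, seq[i : i + L])
        for i, s in _scan_one_strand(seq, model)
    ]
    if both_strands:
        rc = reverse_complement(seq)
        n = len(seq)
        for i, s in _scan_one_strand(rc, model):
            hits.append(MotifHit(contig_id, n - L - i, "-", s / model.max_score, rc[i : i + L]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_genome(
    genome: dict, model: MotifModel, both_strands: bool = True
) -> list[MotifHit]:
    """Scan every contig of a genome mapping (id -> GenomeSequence)."""
    hits = []
    for contig_id, contig in genome.items():
        hits.extend(scan(contig.sequence, model, both_strands, contig_id))
    return hits


def localize_hits(hits: Iterable[MotifHit], genes: Iterable[GeneModel]) -> list[MotifHit]:
    """Assign each hit a gene, region class, CDS offset and codon frame.

    Region is taken from the hit's start position.  ``cds_offset`` (and
    hence frame) is defined only when all motif bases are consecutive in
    the spliced coding sequence; a hit interrupted by an intron keeps
    region CDS but is flagged 'split'.  A hit overlapping two genes is
    assigned to both and flagged 'multi_gene'.  Hits outside any gene are
    returned with region INTERGENIC.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    out: list[MotifHit] = []
    for hit in hits:
        L = len(hit.sequence)
        containing = [
            g
            for g in by_contig.get(hit.contig_id, [])
            if g.span[0] <= hit.start < g.span[1]
        ]
        if not containing:
            out.append(replace_hit(hit, region=RegionClass.INTERGENIC))
            continue
        multi = len(containing) > 1
        for g in containing:
            h = replace_hit(hit, gene_id=g.gene_id, region=g.classify_position(hit.start))
            if multi:
                h.flags = h.flags + ("multi_gene",)
            if h.region is RegionClass.CDS and g.is_coding:
                _fill_cds_offset(h, g, L)
            out.append(h)
    return out


def replace_hit(hit: MotifHit, **kw) -> MotifHit:
    return replace(hit, **kw)


def _fill_cds_offset(hit: MotifHit, gene: GeneModel, L: int) -> None:
    # first motif base in the gene's coding orientation
    if gene.strand == "+":
        first, last = hit.start, hit.start + L - 1
    else:
        first, last = hit.start + L - 1, hit.start
    o_first = gene.cds_offset_of(first)
    o_last = gene.cds_offset_of(last)
    if o_first is None or o_last is None or o_last - o_first != L - 1:
        hit.flags = hit.flags + ("split",)
        return
    hit.cds_offset = o_first
    if gene.coding_sequence is not None:
        hit.coding_sequence = gene.coding_sequence[o_first : o_first + L]
    assign_codon_frame(hit, gene)


def assign_codon_frame(hit: MotifHit, gene: GeneModel) -> Optional[int]:
    """Codon frame of the hit's first coding base: 1 means codon position 1.

    frame = ((cds_offset - phase_offset) mod 3) + 1; undefined (None) when
    the hit has no CDS offset.
    """
    if hit.cds_offset is None:
        return None
    frame = ((hit.cds_offset - gene.coding_phase_offset) % 3) + 1
    hit.codon_frame = frame
    return frame


# ---------------------------------------------------------------------------
# per-gene tabulation

@dataclass(frozen=True)
class PerGeneCounts:
    per_gene: dict[str, int]
    histogram: pd.DataFrame  # motifs_per_gene, n_genes
    total_motifs: int
    fraction_multi: float  # fraction of motif genes with >= 2 hits


def per_gene_counts(hits: Iterable[MotifHit]) -> PerGeneCounts:
    """Hit count per motif-containing gene plus the frequency-of-frequencies table."""
    counts: dict[str, int] = {}
    for h in hits:
        if h.gene_id is not None:
            counts[h.gene_id] = counts.get(h.gene_id, 0) + 1
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    histogram = pd.DataFrame(
        sorted(hist.items()), columns=["motifs_per_gene", "n_genes"]
    )
    total, frac = histogram_summary(hist)
    return PerGeneCounts(counts, histogram, total, frac)


def histogram_summary(hist: dict[int, int]) -> tuple[int, float]:
    """(weighted motif total, fraction of genes with >=2 motifs) of a count histogram."""
    total = sum(k * v for k, v in hist.items())
    n_genes = sum(hist.values())
    multi = sum(v for k, v in hist.items() if k >= 2)
    return total, (multi / n_genes if n_genes else float("nan"))


def cds_preference_test(
    n_cds_hits: float, n_intron_hits: float, cds_bases: float, intron_bases: float
) -> ContingencyResult:
    """Do genic motifs prefer CDS over intron/UTR sequence?

    Expected split of genic hits is proportional to the available base
    composition; 1-df goodness-of-fit chi-square, two-sided.
    """
    if cds_bases <= 0 or intron_bases <= 0:
        raise ValueError("base totals must be positive")
    return gof_chisq(n_cds_hits, n_intron_hits, cds_bases, intron_bases)


# ---------------------------------------------------------------------------
# output formats

def hits_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "contig": h.contig_id,
                "start": h.start,
                "end": h.start + len(h.sequence),
                "strand": h.strand,
                "score_fraction": h.score_fraction,
                "sequence": h.sequence,
                "gene_id": h.gene_id,
                "region": h.region.value if h.region else None,
                "cds_offset": h.cds_offset,
                "codon_frame": h.codon_frame,
                "flags": ",".join(h.flags),
            }
        )
    return pd.DataFrame(rows)


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    """BED6, 0-based half-open; score = 1000 * score_fraction rounded."""
    with open(path, "w") as fh:
        for h in hits:
            name = h.gene_id or "."
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.start + len(h.sequence)}\t{name}"
                f"\t{round(1000 * h.score_fraction)}\t{h.strand}\n"
            )
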
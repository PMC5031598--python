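"""Genic and codon-position GC content.

GC1/GC2/GC3 (collectively GC_x) are the GC fractions over the first,
second and third positions of all codons in a gene's spliced coding
sequence, after removing the leading phase-offset bases that belong to no
complete codon.  Genes are split into high/low GC_x classes at an
inclusive 80% cutoff, the threshold that separates the two modes of the
bimodal GC_x distribution seen in maize and other monocots.

Undefined values (empty sequence, all-N positions) propagate as ``None`` /
``NaN`` and never silently become 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import gaussian_kde

from .genome_io import GeneModel, GenomeSequence

GC_BASES = frozenset("GC")
UNAMBIGUOUS = frozenset("ACGT")

#: inclusive high/low GC_x cutoff
DEFAULT_CUTOFF = 0.80


def gc_fraction(seq: str) -> Optional[float]:
    """(#G + #C) / (#A + #C + #G + #T); ambiguity codes excluded from both counts.

    Returns None (undefined) for an empty denominator rather than 0.
    """
    gc = total = 0
    for b in seq:
        if b in UNAMBIGUOUS:
            total += 1
            if b in GC_BASES:
                gc += 1
    if total == 0:
        return None
    return gc / total


@dataclass(frozen=True)
class CodonPositionGC:
    gc1: Optional[float]
    gc2: Optional[float]
    gc3: Optional[float]
    n_codons: int  # complete codons after the phase trim
    counted_bases: tuple[int, int, int]  # non-N bases entering each position

    def as_tuple(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return self.gc1, self.gc2, self.gc3


def codon_position_gc(
    coding_seq: str, phase_offset: int = 0, include_partial: bool = True
) -> CodonPositionGC:
    """Per-codon-position GC of a spliced coding sequence.

    The first ``phase_offset`` bases are dropped, the remainder is read in
    consecutive triplets, and position *k* collects every k-th triplet
    base.  A trailing partial triplet contributes its present positions by
    default (``include_partial=False`` drops it).
    """
    if phase_offset not in (0, 1, 2):
        raise ValueError(f"phase_offset must be 0, 1 or 2, got {phase_offset}")
    s = coding_seq[phase_offset:]
    if not include_partial:
        s = s[: len(s) - (len(s) % 3)]
    positions = (s[0::3], s[1::3], s[2::3])
    fracs = [gc_fraction(p) for p in positions]
    counted = []
    for p in positions:
        counted.append(sum(1 for b in p if b in UNAMBIGUOUS))
    return CodonPositionGC(
        gc1=fracs[0],
        gc2=fracs[1],
        gc3=fracs[2],
        n_codons=len(s) // 3,
        counted_bases=tuple(counted),
    )


@dataclass(frozen=True)
class GCProfile:
    """Per-gene GC metrics: whole-gene, CDS-only, and per codon position."""

    gene_id: str
    gc_gene: Optional[float]  # exons + introns + UTRs (transcript span)
    gc_cds: Optional[float]  # spliced coding sequence only
    gc1: Optional[float]
    gc2: Optional[float]
    gc3: Optional[float]
    n_codons: int
    counted_bases: tuple[int, int, int]


def gc_profile(gene: GeneModel, genome: GenomeSequence, include_partial: bool = True) -> GCProfile:
    """Compute the full GC profile of one coding gene.

    ``gc_gene`` spans transcription start to stop of the representative
    transcript (introns and UTRs included); ``gc_cds`` and GC_x use only
    the spliced coding sequence, phase respected.
    """
    if gene.coding_sequence is None:
        from .genome_io import assemble_coding_sequence

        assemble_coding_sequence(gene, genome)
    start, end = gene.span
    cpg = codon_position_gc(gene.coding_sequence, gene.coding_phase_offset, include_partial)
    return GCProfile(
        gene_id=gene.gene_id,
        gc_gene=gc_fraction(genome.sequence[start:end]),
        gc_cds=gc_fraction(gene.coding_sequence),
        gc1=cpg.gc1,
        gc2=cpg.gc2,
        gc3=cpg.gc3,
        n_codons=cpg.n_codons,
        counted_bases=cpg.counted_bases,
    )


@dataclass(frozen=True)
class GCClassLabel:
    """High/low class membership per codon position; None when GC_x is undefined."""

    gene_id: str
    high_gc1: Optional[bool]
    high_gc2: Optional[bool]
    high_gc3: Optional[bool]


def classify_gcx(profile: GCProfile, cutoff: float = DEFAULT_CUTOFF) -> GCClassLabel:
    """Label a gene high in GC_x iff gc_x >= cutoff (inclusive boundary)."""

    def lab(v: Optional[float]) -> Optional[bool]:
        return None if v is None else bool(v >= cutoff)

    return GCClassLabel(profile.gene_id, lab(profile.gc1), lab(profile.gc2), lab(profile.gc3))


def labels_frame(labels: Iterable[GCClassLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "high_gc1": l.high_gc1,
                "high_gc2": l.high_gc2,
                "high_gc3": l.high_gc3,
            }
            for l in labels
        ]
    )


def class_counts(labels: Iterable[GCClassLabel]) -> pd.DataFrame:
    """High/low gene counts per GC_x (genes with undefined GC_x excluded per row)."""
    labels = list(labels)
    rows = []
    for pos, attr in ((1, "high_gc1"), (2, "high_gc2"), (3, "high_gc3")):
        vals = [getattr(l, attr) for l in labels if getattr(l, attr) is not None]
        rows.append({"gcx": f"gc{pos}", "n_high": sum(vals), "n_low": len(vals) - sum(vals)})
    return pd.DataFrame(rows).set_index("gcx")


def pairwise_class_overlap(
    labels: Iterable[GCClassLabel], profiles: Optional[Iterable[GCProfile]] = None
) -> dict:
    """Counts of genes high in both classes for pairs (1,2), (1,3), (2,3).

    When profiles are supplied, raw (gc_a, gc_b) scatter pairs are
    returned alongside for plotting.
    """
    labels = list(labels)
    overlaps = {}
    for a, b in ((1, 2), (1, 3), (2, 3)):
        overlaps[(a, b)] = sum(
            1
            for l in labels
            if getattr(l, f"high_gc{a}") and getattr(l, f"high_gc{b}")
        )
    result = {"overlaps": overlaps}
    if profiles is not None:
        profiles = list(profiles)
        scatter = {}
        for a, b in ((1, 2), (1, 3), (2, 3)):
            pairs = [
                (getattr(p, f"gc{a}"), getattr(p, f"gc{b}"))
                for p in profiles
                if getattr(p, f"gc{a}") is not None and getattr(p, f"gc{b}") is not None
            ]
            scatter[(a, b)] = pairs
        result["scatter"] = scatter
    return result


def gc_density(
    values: Sequence[float], bandwidth: Optional[float] = None, grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of GC fractions on [0, 1], renormalized to unit area.

    Bandwidth defaults to Scott's rule.  A degenerate all-equal sample gets
    a narrow Gaussian centred on the common value so that the single-peak
    case stays well defined.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size < 2:
        raise ValueError("gc_density requires at least 2 defined values")
    grid = np.linspace(0.0, 1.0, grid_size)
    if np.ptp(vals) == 0.0:
        bw = bandwidth or 0.01
        dens = np.exp(-0.5 * ((grid - vals[0]) / bw) ** 2)
    else:
        kde = gaussian_kde(vals, bw_method=bandwidth)
        dens = kde(grid)
    area = np.trapezoid(dens, grid)
    return grid, dens / area


@dataclass(frozen=True)
class DegeneracyProfile:
    """Per-codon-position degeneracy of the standard genetic code.

    ``position_counts[k]`` is the number of codons (of 64) for which at
    least one substitution at position k+1 is synonymous.  Stop codons are
    treated as their own class (a stop-to-stop change is synonymous).
    """

    position_counts: tuple[int, int, int]
    per_codon: dict[str, tuple[bool, bool, bool]]


def degeneracy_profile() -> DegeneracyProfile:
    table = CodonTable.unambiguous_dna_by_id[1]
    stops = set(table.stop_codons)

    def product_of(codon: str) -> str:
        return "*" if codon in stops else table.forward_table[codon]

    bases = "ACGT"
    per_codon = {}
    counts = [0, 0, 0]
    for codon in ("".join(c) for c in product(bases, repeat=3)):
        aa = product_of(codon)
        flags = []
        for k in range(3):
            syn = any(
                product_of(codon[:k] + b + codon[k + 1 :]) == aa for b in bases if b != codon[k]
            )
            flags.append(syn)
            if syn:
                counts[k] += 1
        per_codon[codon] = tuple(flags)
    return DegeneracyProfile(tuple(counts), per_codon)


def profiles_frame(profiles: Iterable[GCProfile], cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Tidy per-gene table: GC metrics plus high/low flags at ``cutoff``."""
    rows = []
    for p in profiles:
        lab = classify_gcx(p, cutoff)
        rows.append(
            {
                "gene_id": p.gene_id,
                "gc_gene": p.gc_gene,
                "gc_cds": p.gc_cds,
                "gc1": p.gc1,
                "gc2": p.gc2,
                "gc3": p.gc3,
                "n_codons": p.n_codons,
                "high_gc1": lab.high_gc1,
                "high_gc2": lab.high_gc2,
                "high_gc3": lab.high_gc3,
            }
        )
    return pd.DataFrame(rows)
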
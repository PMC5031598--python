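"""GC statistics of motif instances: 3-nt periodicity and codon-frame views.

Two coordinate systems coexist.  *Motif coordinates* group positions
1..19 into three periodicity groups (1,4,7,...; 2,5,8,...; 3,6,9,...)
relative to the motif start.  *Codon coordinates* shift each instance by
its codon frame so bases land in GC1/GC2/GC3 bins of the host gene's
reading frame, trimming the end overhangs that the shift produces so only
complete codon columns remain.

Group comparisons follow a variance-gated procedure: a two-sided F-test
for equal variance routes the comparison to a pooled (homoscedastic) or
Welch (heteroscedastic) two-tailed t-test.  The gate alpha defaults to
0.10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_gc import gc_density, gc_fraction
from .motif_scan import MotifHit

#: 0-based motif position indices per periodicity group
PERIODICITY_GROUPS: dict[int, tuple[int, ...]] = {
    1: tuple(range(0, 19, 3)),  # positions 1,4,...,19 (7 values)
    2: tuple(range(1, 19, 3)),  # positions 2,5,...,17 (6 values)
    3: tuple(range(2, 19, 3)),  # positions 3,6,...,18 (6 values)
}


def per_position_gc(sequences: Iterable[str]) -> np.ndarray:
    """GC fraction at each of the 19 motif positions across all instances.

    N bases are excluded from numerator and denominator at their position.
    """
    seqs = [s.upper() for s in (h.sequence if isinstance(h, MotifHit) else h for h in sequences)]
    if not seqs:
        raise ValueError("per_position_gc requires at least one motif instance")
    L = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(len(seqs), L)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    with np.errstate(invalid="ignore"):
        return is_gc.sum(axis=0) / is_acgt.sum(axis=0)


def periodicity_group_stats(per_position: Sequence[float]) -> dict[int, np.ndarray]:
    """Split 19 per-position GC values into the three fixed periodicity groups."""
    pp = np.asarray(per_position, dtype=float)
    if pp.shape != (19,):
        raise ValueError(f"expected 19 per-position values, got shape {pp.shape}")
    return {g: pp[list(idx)] for g, idx in PERIODICITY_GROUPS.items()}


@dataclass(frozen=True)
class MotifGcxProfile:
    """Per-instance GC1/GC2/GC3 after frame shift and overhang trimming."""

    gene_id: Optional[str]
    gc1: Optional[float]
    gc2: Optional[float]
    gc3: Optional[float]
    n_bases: tuple[int, int, int]


def motif_codon_gcx(hit: MotifHit) -> Optional[MotifGcxProfile]:
    """Place motif bases into codon-position bins of the host gene.

    Base i (1-indexed) of an instance in frame f occupies codon position
    ((f - 1 + i - 1) mod 3) + 1.  Leading bases before the first complete
    codon and trailing bases after the last complete codon are trimmed.
    Returns None for hits without a defined frame.
    """
    if hit.codon_frame is None:
        return None
    seq = hit.coding_sequence or hit.sequence
    L = len(seq)
    cpos = [((hit.codon_frame - 1 + i) % 3) for i in range(L)]  # 0-based codon positions
    try:
        first = next(i for i in range(L) if cpos[i] == 0)
        last = next(i for i in range(L - 1, -1, -1) if cpos[i] == 2)
    except StopIteration:
        return None
    if last <= first:
        return None
    bins = {0: [], 1: [], 2: []}
    for i in range(first, last + 1):
        bins[cpos[i]].append(seq[i])
    gcs = [gc_fraction("".join(bins[k])) for k in range(3)]
    return MotifGcxProfile(
        gene_id=hit.gene_id,
        gc1=gcs[0],
        gc2=gcs[1],
        gc3=gcs[2],
        n_bases=tuple(len(bins[k]) for k in range(3)),
    )


@dataclass(frozen=True)
class VarianceGatedTTestResult:
    f_statistic: float
    f_test_p: float
    variance_equal: bool
    t_test_kind: str  # 'pooled' or 'welch'
    t_statistic: float
    t_p_two_sided: float


def variance_gated_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float], f_alpha: float = 0.10
) -> VarianceGatedTTestResult:
    """Two-sided F-test for equal variance gating a two-tailed t-test.

    If the F p-value falls below ``f_alpha`` the comparison uses Welch's
    unequal-variance t-test, otherwise the pooled equal-variance t-test
    (the spreadsheet F.TEST / T.TEST convention).  Two zero-variance
    samples with equal means report t=0, p=1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        f_stat, f_p = float("nan"), 1.0
        equal = True
        if a.mean() == b.mean():
            return VarianceGatedTTestResult(f_stat, f_p, True, "pooled", 0.0, 1.0)
        return VarianceGatedTTestResult(f_stat, f_p, True, "pooled", float("inf"), 0.0)
    if vb == 0 or va == 0:
        # infinite variance ratio: variances differ as strongly as possible
        f_stat, f_p = float("inf"), 0.0
    else:
        f_stat = va / vb
        cdf = stats.f.cdf(f_stat, a.size - 1, b.size - 1)
        f_p = float(min(1.0, 2 * min(cdf, 1 - cdf)))
    equal = f_p >= f_alpha
    import warnings

    with warnings.catch_warnings():
        # near-identical samples trip scipy's catastrophic-cancellation warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=equal)
    return VarianceGatedTTestResult(
        f_statistic=float(f_stat),
        f_test_p=f_p,
        variance_equal=equal,
        t_test_kind="pooled" if equal else "welch",
        t_statistic=float(t_stat),
        t_p_two_sided=float(t_p),
    )


def group_comparison_table(
    groups: dict[str, Sequence[float]],
    pairs: Iterable[tuple[str, str]],
    f_alpha: float = 0.10,
) -> pd.DataFrame:
    """Pairwise variance-gated comparisons, one row per pair (Table-3 layout)."""
    rows = []
    for a, b in pairs:
        res = variance_gated_t_test(groups[a], groups[b], f_alpha)
        rows.append(
            {
                "comparison": f"{a} vs. {b}",
                "f_test_p": res.f_test_p,
                "t_test_kind": res.t_test_kind,
                "pooled_t_p": res.t_p_two_sided if res.t_test_kind == "pooled" else np.nan,
                "welch_t_p": res.t_p_two_sided if res.t_test_kind == "welch" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def codon_position_group_samples(hits: Iterable[MotifHit]) -> dict[str, list[float]]:
    """Per-position GC samples in codon coordinates, for group comparisons.

    For each motif position j and codon position k, the GC fraction is
    computed over all (frame-defined, trimmed) instances whose base j maps
    to codon position k; the sample for codon position k is the set of
    those per-position values.  This keeps the unit of observation the
    per-position GC value, matching the periodicity-group analyses.
    """
    gc_count: dict[tuple[int, int], int] = {}
    n_count: dict[tuple[int, int], int] = {}
    for hit in hits:
        if hit.codon_frame is None:
            continue
        seq = (hit.coding_sequence or hit.sequence).upper()
        L = len(seq)
        cpos = [((hit.codon_frame - 1 + i) % 3) for i in range(L)]
        try:
            first = next(i for i in range(L) if cpos[i] == 0)
            last = next(i for i in range(L - 1, -1, -1) if cpos[i] == 2)
        except StopIteration:
            continue
        for i in range(first, last + 1):
            if seq[i] not in "ACGT":
                continue
            key = (i, cpos[i])
            n_count[key] = n_count.get(key, 0) + 1
            if seq[i] in "GC":
                gc_count[key] = gc_count.get(key, 0) + 1
    samples: dict[str, list[float]] = {"gc1": [], "gc2": [], "gc3": []}
    for (j, k), n in sorted(n_count.items()):
        samples[f"gc{k + 1}"].append(gc_count.get((j, k), 0) / n)
    return samples


def per_motif_gcx_density(
    profiles: Iterable[MotifGcxProfile], bandwidth: Optional[float] = None
) -> dict[str, dict]:
    """Density of per-instance GC1/GC2/GC3 plus the fraction at exactly 1.0."""
    profiles = [p for p in profiles if p is not None]
    out = {}
    for k in (1, 2, 3):
        vals = [getattr(p, f"gc{k}") for p in profiles if getattr(p, f"gc{k}") is not None]
        if len(vals) < 2:
            raise ValueError(f"per_motif_gcx_density requires >=2 defined gc{k} values")
        grid, dens = gc_density(vals, bandwidth)
        out[f"gc{k}"] = {
            "grid": grid,
            "density": dens,
            "fraction_at_1": float(np.mean(np.asarray(vals) == 1.0)),
            "values": np.asarray(vals),
        }
    return out


def profiles_frame(profiles: Iterable[Optional[MotifGcxProfile]]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        if p is None:
            continue
        rows.append(
            {
                "gene_id": p.gene_id,
                "gc1": p.gc1,
                "gc2": p.gc2,
                "gc3": p.gc3,
                "n1": p.n_bases[0],
                "n2": p.n_bases[1],
                "n3": p.n_bases[2],
            }
        )
    return pd.DataFrame(rows)
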
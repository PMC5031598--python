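"""Genome-proportion contingency tests.

Every enrichment question in the analysis reduces to the same 1-df
goodness-of-fit chi-square: a gene subset of size *n* is split into a
"yes" and a "no" cell, the expected split is taken from genome-wide (or
universe-wide) proportions at full floating-point precision, and the
statistic is sum((O-E)^2 / E) with a two-sided upper-tail p on 1 df, no
continuity correction.  Expectations are deliberately *not* rounded:
reproducing published p-values requires the unrounded expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import chi2 as chi2_dist

UNDERFLOW = 1e-300


@dataclass(frozen=True)
class ContingencyResult:
    """Observed/expected yes-no counts with the chi-square verdict."""

    observed: tuple[float, float]
    expected: tuple[float, float]
    chi2: float
    p: float
    df: int = 1

    @property
    def p_display(self) -> str:
        """p formatted for reports; underflow shown as '< 1e-300'."""
        if self.p < UNDERFLOW:
            return "< 1e-300"
        return f"{self.p:.6g}"


def gof_chisq(
    observed_yes: float, observed_no: float, universe_yes: float, universe_no: float
) -> ContingencyResult:
    """Goodness-of-fit chi-square of a yes/no split against universe proportions.

    Expected yes = n * universe_yes / (universe_yes + universe_no), kept at
    full precision.  Raises on negative counts or a zero expected cell.
    """
    for name, v in (
        ("observed_yes", observed_yes),
        ("observed_no", observed_no),
        ("universe_yes", universe_yes),
        ("universe_no", universe_no),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    universe_total = universe_yes + universe_no
    if universe_total <= 0:
        raise ValueError("universe total must be positive")
    n = observed_yes + observed_no
    e_yes = n * universe_yes / universe_total
    e_no = n - e_yes
    if e_yes == 0 or e_no == 0:
        raise ValueError(f"zero expected cell: expected=({e_yes}, {e_no})")
    chi2 = (observed_yes - e_yes) ** 2 / e_yes + (observed_no - e_no) ** 2 / e_no
    p = float(chi2_dist.sf(chi2, df=1))
    return ContingencyResult(
        observed=(observed_yes, observed_no), expected=(e_yes, e_no), chi2=float(chi2), p=p
    )


def expected_overlap(n_class_a: float, n_class_b: float, n_genome: float) -> tuple[float, int]:
    """Expected co-membership count under random sampling: a*b/n.

    Returns (unrounded, rounded-to-nearest-int).
    """
    if n_class_a < 0 or n_class_b < 0:
        raise ValueError("class counts must be non-negative")
    if n_genome <= 0:
        raise ValueError("n_genome must be positive")
    exact = n_class_a * n_class_b / n_genome
    return exact, round(exact)


# ---------------------------------------------------------------------------
# label-collection analyses

_GCX = ("gc1", "gc2", "gc3")


def _high_sets(labels: pd.DataFrame) -> dict[str, set]:
    """Gene-id sets high per GC_x from a labels frame (gene_id, high_gc1..3)."""
    out = {}
    for g in _GCX:
        col = labels[f"high_{g}"]
        out[g] = set(labels.loc[col.fillna(False).astype(bool), "gene_id"])
    return out


def motif_gcx_tests(motif_genes: Iterable[str], labels: pd.DataFrame) -> pd.DataFrame:
    """High/low GC_x enrichment among motif-containing genes.

    One row per GC_x: observed high/low counts among motif genes versus
    expectations from genome-wide class proportions.
    """
    import warnings

    motif_genes = set(motif_genes)
    high = _high_sets(labels)
    rows = []
    for g in _GCX:
        defined = labels[labels[f"high_{g}"].notna()]
        uni_high = len(high[g])
        uni_low = len(defined) - uni_high
        if uni_high == 0 or uni_low == 0:
            warnings.warn(f"degenerate genome-wide high_{g} split; test skipped", stacklevel=2)
            continue
        obs_high = len(motif_genes & high[g])
        obs_low = len(motif_genes & set(defined["gene_id"])) - obs_high
        res = gof_chisq(obs_high, obs_low, uni_high, uni_low)
        rows.append(_result_row(g, res))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def class_overlap_tests(labels: pd.DataFrame) -> pd.DataFrame:
    """GC_x class co-occurrence: is class B randomly distributed within high-A genes?

    For each conditioning class (high GC1/GC2/GC3) and each *other* class,
    the observed within-class membership is tested against genome-wide
    proportions.  Empty conditioning classes are skipped with a warning row.
    """
    import warnings

    high = _high_sets(labels)
    n_genome = {g: int(labels[f"high_{g}"].notna().sum()) for g in _GCX}
    rows = []
    for cond in _GCX:
        cond_set = high[cond]
        if not cond_set:
            warnings.warn(f"empty conditioning class high_{cond}; skipped", stacklevel=2)
            continue
        for other in _GCX:
            if other == cond:
                continue
            uni_high = len(high[other])
            if uni_high == 0 or uni_high == n_genome[other]:
                warnings.warn(
                    f"degenerate genome-wide high_{other} split; comparison skipped",
                    stacklevel=2,
                )
                continue
            obs_high = len(cond_set & high[other])
            obs_low = len(cond_set) - obs_high
            res = gof_chisq(obs_high, obs_low, uni_high, n_genome[other] - uni_high)
            rows.append(_result_row(f"{other}_within_high_{cond}", res))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


@dataclass
class ExpressionLabelSet:
    """Differential-expression labels consumed as input, not recomputed.

    ``labels`` has columns gene_id, direction ('up'/'down'), comparison
    ('anther'/'seedling'); ``universe`` is the gene universe the fractions
    are taken over.  A gene may not be both up and down in the same
    comparison.
    """

    labels: pd.DataFrame
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.labels):
            dup = (
                self.labels.groupby(["gene_id", "comparison"])["direction"].nunique()
            )
            bad = dup[dup > 1]
            if len(bad):
                raise ValueError(
                    f"genes both up and down in one comparison: {list(bad.index)[:5]}"
                )

    def genes(self, direction: str, comparison: str) -> set:
        m = (self.labels["direction"] == direction) & (self.labels["comparison"] == comparison)
        return set(self.labels.loc[m, "gene_id"])

    @classmethod
    def read_tsv(cls, path, universe: Optional[Iterable[str]] = None) -> "ExpressionLabelSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "direction", "comparison"}
        if not required.issubset(df.columns):
            raise ValueError(f"expression label TSV needs columns {sorted(required)}")
        return cls(df, set(universe) if universe is not None else set(df["gene_id"]))


def expression_bias_tests(
    motif_genes: Iterable[str],
    expression: ExpressionLabelSet,
    gc_labels: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Expression-class contingency analyses.

    Returns two tables:

    - ``motif_expression``: within motif-containing genes, are up- (resp.
      down-) regulated genes over/under-represented relative to their
      universe fraction?
    - ``expression_gcx``: within each expression class, are high-GC_x
      genes over/under-represented relative to genome-wide proportions?

    Genes absent from the universe are excluded and logged.
    """
    import logging

    log = logging.getLogger(__name__)
    universe = expression.universe
    motif_genes = set(motif_genes)
    missing = motif_genes - universe
    if missing:
        log.info("excluding %d motif genes absent from universe", len(missing))
        motif_genes = motif_genes & universe
    n_universe = len(universe)

    rows6 = []
    for direction in ("up", "down") if motif_genes else ():
        for comparison in sorted(set(expression.labels["comparison"])):
            labeled = expression.genes(direction, comparison) & universe
            if not labeled or len(labeled) == n_universe:
                continue
            obs_yes = len(motif_genes & labeled)
            obs_no = len(motif_genes) - obs_yes
            res = gof_chisq(obs_yes, obs_no, len(labeled), n_universe - len(labeled))
            rows6.append(_result_row(f"{direction}_vs_{comparison}", res))
    table6 = pd.DataFrame(rows6, columns=_RESULT_COLUMNS)

    high = _high_sets(gc_labels)
    defined = {g: set(gc_labels.loc[gc_labels[f"high_{g}"].notna(), "gene_id"]) for g in _GCX}
    rows7 = []
    classes = [("all_expressed", universe)]
    for direction in ("up", "down"):
        for comparison in sorted(set(expression.labels["comparison"])) or []:
            genes = expression.genes(direction, comparison) & universe
            if genes:
                classes.append((f"{direction}_vs_{comparison}", genes))
    for name, genes in classes:
        for g in _GCX:
            in_def = genes & defined[g]
            uni_high = len(high[g])
            if not in_def or uni_high == 0 or uni_high == len(defined[g]):
                continue
            obs_high = len(in_def & high[g])
            obs_low = len(in_def) - obs_high
            res = gof_chisq(obs_high, obs_low, uni_high, len(defined[g]) - uni_high)
            rows7.append(_result_row(f"{name}_{g}", res))
    table7 = pd.DataFrame(rows7, columns=_RESULT_COLUMNS)
    return {"motif_expression": table6, "expression_gcx": table7}


_RESULT_COLUMNS = [
    "condition",
    "observed_yes",
    "expected_yes",
    "observed_no",
    "expected_no",
    "chi2",
    "p",
    "p_display",
]


def _result_row(condition: str, res: ContingencyResult) -> dict:
    return {
        "condition": condition,
        "observed_yes": res.observed[0],
        "expected_yes": res.expected[0],
        "observed_no": res.observed[1],
        "expected_no": res.expected[1],
        "chi2": res.chi2,
        "p": res.p,
        "p_display": res.p_display,
    }
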
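"""Per-dataset summaries, clonality statistics and dataset comparisons.

The summary mirrors the pipeline funnel — raw reads, primer-filtered reads,
per-round unique alignments, unique integration sites, per-category counts
and percentages — plus the mean IS read coverage (final aligned reads per
unique site), a proxy for clonal abundance under PCR duplication.  Datasets
are compared per category with a two-sided Fisher's exact test
(category count vs the rest, dataset A vs B).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .align_filter import RoundSummary
from .annotate import AnnotatedSite, Category
from .primer_trim import TrimStats

CATEGORIES = (Category.TSS_PROXIMAL, Category.INTRAGENIC, Category.INTERGENIC)


@dataclass
class DatasetSummary:
    n_raw: int
    n_filtered: int
    round_counts: RoundSummary
    n_unique_is: int
    category_counts: Dict[Category, int]
    category_fractions: Dict[Category, Optional[float]]
    mean_coverage: Optional[float]


@dataclass(frozen=True)
class GeneISCount:
    symbol: str
    n_sites: int


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (so 24.5 -> 25 at 0 decimals)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 0) -> float:
    """100 * count / total, rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("percentage: total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def mean_coverage(n_aligned: int, n_sites: int, decimals: int = 1) -> float:
    """Mean supporting reads per unique integration site."""
    if n_sites <= 0:
        raise ValueError("mean_coverage: n_sites must be positive")
    return round_half_up(n_aligned / n_sites, decimals)


def summarize(
    trim_stats: TrimStats,
    rounds: RoundSummary,
    annotated: Sequence[AnnotatedSite],
    decimals: int = 0,
    coverage_decimals: int = 1,
) -> DatasetSummary:
    """Assemble the per-dataset funnel/category summary.

    With zero unique sites, fractions and mean coverage are None (reported
    as NA) rather than a division error.
    """
    n_is = len(annotated)
    counts = {c: 0 for c in CATEGORIES}
    for a in annotated:
        counts[a.category] += 1
    if n_is > 0:
        fractions = {c: percentage(counts[c], n_is, decimals) for c in CATEGORIES}
        cov = mean_coverage(rounds.n_unique_mm2, n_is, coverage_decimals)
    else:
        fractions = {c: None for c in CATEGORIES}
        cov = None
    return DatasetSummary(
        n_raw=trim_stats.n_input,
        n_filtered=trim_stats.n_after_minlen,
        round_counts=rounds,
        n_unique_is=n_is,
        category_counts=counts,
        category_fractions=fractions,
        mean_coverage=cov,
    )


def top_genes(annotated: Sequence[AnnotatedSite], n: int = 20) -> List[GeneISCount]:
    """Top-N genes by number of unique ISs attributed to them.

    Only TSS-proximal and intragenic sites count (intergenic sites report a
    nearest gene but are not gene-contained).  Sites are tallied per gene
    symbol; ties order alphabetically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tally: Dict[str, int] = {}
    for a in annotated:
        if a.category in (Category.TSS_PROXIMAL, Category.INTRAGENIC) and a.symbol:
            tally[a.symbol] = tally.get(a.symbol, 0) + 1
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [GeneISCount(sym, cnt) for sym, cnt in ranked[:n]]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]].

    Probability-mass definition: with margins fixed, sum the hypergeometric
    probabilities of every table no more likely than the observed one.
    Computed in log space, stable for totals up to ~10^6.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be >= 0")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    row1 = a + b
    col1 = a + c
    kmin = max(0, row1 - (n - col1))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    logp = hypergeom.logpmf(ks, n, col1, row1)
    log_obs = hypergeom.logpmf(a, n, col1, row1)
    # relative tolerance absorbs floating-point noise in the pmf comparison
    mask = logp <= log_obs + 1e-7
    if mask.all():
        # every fixed-margin outcome qualifies; the mass sums to 1 exactly
        return 1.0
    p = float(np.exp(logp[mask]).sum())
    return min(1.0, p)


def compare_categories(
    a: DatasetSummary, b: DatasetSummary
) -> Dict[Category, float]:
    """Per-category Fisher comparison of two datasets.

    Each category forms the 2x2 table (in-category vs rest, dataset a vs b).
    """
    if a.n_unique_is <= 0 or b.n_unique_is <= 0:
        raise ValueError("both datasets must have at least one unique IS")
    out = {}
    for cat in CATEGORIES:
        ca, cb = a.category_counts[cat], b.category_counts[cat]
        out[cat] = fisher_exact_2x2(
            ca, a.n_unique_is - ca, cb, b.n_unique_is - cb
        )
    return out


# ---------------------------------------------------------------------------
# summary table serialization (consumed by the compare subcommand)

_NA = "NA"


def write_summary_tsv(summary: DatasetSummary, path) -> None:
    rows = [
        ("n_raw", summary.n_raw),
        ("n_filtered", summary.n_filtered),
        ("n_unique_mm0", summary.round_counts.n_unique_mm0),
        ("n_unique_mm1", summary.round_counts.n_unique_mm1),
        ("n_unique_mm2", summary.round_counts.n_unique_mm2),
        ("n_unique_is", summary.n_unique_is),
    ]
    for cat in CATEGORIES:
        rows.append((f"n_{cat.name.lower()}", summary.category_counts[cat]))
    for cat in CATEGORIES:
        frac = summary.category_fractions[cat]
        rows.append((f"pct_{cat.name.lower()}", _NA if frac is None else frac))
    rows.append(
        ("mean_coverage", _NA if summary.mean_coverage is None else summary.mean_coverage)
    )
    with open(path, "w") as out:
        out.write("metric\tvalue\n")
        for key, value in rows:
            out.write(f"{key}\t{value}\n")


def read_summary_tsv(path) -> DatasetSummary:
    from .formats_io import FormatError

    values: Dict[str, str] = {}
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("metric"):
            raise FormatError(f"{path}: missing summary header")
        for line in handle:
            if not line.strip():
                continue
            try:
                key, value = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise FormatError(f"{path}: malformed summary line {line!r}") from exc
            values[key] = value

    def _int(key: str) -> int:
        try:
            return int(values[key])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: missing or non-integer {key}") from exc

    n_is = _int("n_unique_is")
    counts = {c: _int(f"n_{c.name.lower()}") for c in CATEGORIES}
    fractions = {
        c: None if values.get(f"pct_{c.name.lower()}", _NA) == _NA
        else float(values[f"pct_{c.name.lower()}"])
        for c in CATEGORIES
    }
    cov = values.get("mean_coverage", _NA)
    return DatasetSummary(
        n_raw=_int("n_raw"),
        n_filtered=_int("n_filtered"),
        round_counts=RoundSummary(
            n_input=_int("n_filtered"),
            n_unique_mm0=_int("n_unique_mm0"),
            n_unique_mm1=_int("n_unique_mm1"),
            n_unique_mm2=_int("n_unique_mm2"),
        ),
        n_unique_is=n_is,
        category_counts=counts,
        category_fractions=fractions,
        mean_coverage=None if cov == _NA else float(cov),
    )


def write_top_genes_tsv(gene_counts: Sequence[GeneISCount], path) -> None:
    with open(path, "w") as out:
        out.write("symbol\tn_sites\n")
        for gc in gene_counts:
            out.write(f"{gc.symbol}\t{gc.n_sites}\n")


def write_comparisons_tsv(
    a: DatasetSummary, b: DatasetSummary, pvalues: Dict[Category, float], path
) -> None:
    with open(path, "w") as out:
        out.write("category\ta_count\ta_total\tb_count\tb_total\tp_value\n")
        for cat in CATEGORIES:
            out.write(
                f"{cat.name}\t{a.category_counts[cat]}\t{a.n_unique_is}\t"
                f"{b.category_counts[cat]}\t{b.n_unique_is}\t{pvalues[cat]:.6g}\n"
            )
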
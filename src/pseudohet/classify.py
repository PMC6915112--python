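"""Per-locus classification, parent-pattern partitioning and segregation tests.

In a haploid mapping population every individual carries a single allele
per single-copy locus, so a genotype matrix of haploid gametophytes should
contain only homozygous (and missing) calls, with the two parental alleles
segregating 1:1 among offspring wherever the parents differ.  Heterozygous
calls therefore flag loci whose reads plausibly derive from two collapsed
paralogous copies (pseudo-heterozygosity).  This module implements the
bookkeeping around that signal:

* a missing-rate locus filter,
* the two top-level locus classes (heterozygous-in-any-individual vs
  uniformly homozygous) plus the identical-heterozygous-in-all flag,
* the parent-genotype partition used to route loci to different
  source-exclusion screens,
* a Pearson chi-square test of the expected 1:1 offspring segregation at
  loci where the parents are homozygous for different alleles,
* per-individual genotype-composition statistics, and
* a tally of per-sequence species annotations.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .errors import ClassificationError, UsageError
from .model import HET, HOM_ALT, HOM_REF, MISSING, Call, GenotypeMatrix

__all__ = [
    "LocusClassValue",
    "LocusClass",
    "ParentPattern",
    "IndividualStats",
    "SegregationResult",
    "AnnotationTally",
    "filter_missing_rate",
    "classify_locus",
    "classify_matrix",
    "parent_pattern",
    "parent_patterns",
    "per_individual_stats",
    "classification_summary",
    "segregation_test",
    "summarize_annotation",
    "expand_annotation_counts",
]


class LocusClassValue(enum.Enum):
    UNIFORM_HOMOZYGOUS = "UNIFORM_HOMOZYGOUS"
    HETEROZYGOUS_ANY = "HETEROZYGOUS_ANY"


@dataclass(frozen=True)
class LocusClass:
    value: LocusClassValue
    identical_het_all: bool

    def __post_init__(self) -> None:
        if self.identical_het_all and self.value is not LocusClassValue.HETEROZYGOUS_ANY:
            raise ValueError("identical_het_all implies HETEROZYGOUS_ANY")


class ParentPattern(enum.Enum):
    BOTH_HET_IDENTICAL = "BOTH_HET_IDENTICAL"
    ONE_PARENT_HET = "ONE_PARENT_HET"
    PARENTS_HOM_DIFFERENT = "PARENTS_HOM_DIFFERENT"
    PARENTS_HOM_SAME = "PARENTS_HOM_SAME"
    OTHER = "OTHER"


def filter_missing_rate(matrix: GenotypeMatrix, max_rate: float = 0.15) -> tuple:
    """Keep loci whose missing-call fraction is strictly below ``max_rate``.

    Returns ``(kept_matrix, n_removed)``; locus order is preserved.
    """
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError(f"max_rate must be in [0, 1], got {max_rate}")
    if matrix.n_loci == 0:
        return matrix, 0
    miss = (matrix.codes == MISSING).mean(axis=1)
    keep = np.flatnonzero(miss < max_rate)
    return matrix.subset_loci(keep), matrix.n_loci - len(keep)


def classify_locus(calls, *, identical_requires_complete: bool = True) -> LocusClass:
    """Assign the top-level class for one locus's calls.

    A locus is HETEROZYGOUS_ANY when at least one call is heterozygous;
    otherwise it is UNIFORM_HOMOZYGOUS (all-homozygous or homozygous plus
    missing).  ``identical_het_all`` is true when every individual is
    heterozygous with the same allele pair; under the strict reading
    (default) a single missing call disqualifies the locus, under the
    relaxed reading (``identical_requires_complete=False``) missing calls
    are tolerated as long as every non-missing call is heterozygous.
    """
    calls = list(calls)
    if not calls:
        raise ClassificationError("locus has no calls")
    if all(c.is_missing for c in calls):
        raise ClassificationError("all calls missing: locus is uninformative")
    het_pairs = {c.alleles for c in calls if c.is_het}
    if not het_pairs:
        return LocusClass(LocusClassValue.UNIFORM_HOMOZYGOUS, False)
    n_het = sum(c.is_het for c in calls)
    n_missing = sum(c.is_missing for c in calls)
    same_pair = len(het_pairs) == 1
    if identical_requires_complete:
        identical = same_pair and n_het == len(calls)
    else:
        identical = same_pair and n_het + n_missing == len(calls)
    return LocusClass(LocusClassValue.HETEROZYGOUS_ANY, identical)


def _all_missing_rows(matrix: GenotypeMatrix) -> np.ndarray:
    return np.flatnonzero((matrix.codes == MISSING).all(axis=1))


def classify_matrix(
    matrix: GenotypeMatrix, *, identical_requires_complete: bool = True
) -> pd.DataFrame:
    """Vectorised per-locus classification over the whole matrix.

    Returns a DataFrame with columns scaffold, position, het_any,
    identical_het_all (one row per locus, matrix order).  Biallelic loci
    make the "same allele pair" condition automatic, so only call
    categories matter here.
    """
    bad = _all_missing_rows(matrix)
    if bad.size:
        raise ClassificationError(
            f"{bad.size} loci have all calls missing (first: {matrix.loci[bad[0]].id}); "
            "remove them with filter_missing_rate first"
        )
    codes = matrix.codes
    het_any = (codes == HET).any(axis=1)
    if identical_requires_complete:
        identical = (codes == HET).all(axis=1)
    else:
        identical = ((codes == HET) | (codes == MISSING)).all(axis=1) & het_any
    return pd.DataFrame(
        {
            "scaffold": [l.scaffold for l in matrix.loci],
            "position": [l.position for l in matrix.loci],
            "het_any": het_any,
            "identical_het_all": identical,
        }
    )


def parent_pattern(locus_index: int, matrix: GenotypeMatrix) -> ParentPattern:
    """Partition one locus by the genotypes of the two parents."""
    f, m = int(matrix.codes[locus_index, 0]), int(matrix.codes[locus_index, 1])
    return _pattern_from_codes(f, m)


def _pattern_from_codes(f: int, m: int) -> ParentPattern:
    f_het, m_het = f == HET, m == HET
    f_hom, m_hom = f in (HOM_REF, HOM_ALT), m in (HOM_REF, HOM_ALT)
    if f_het and m_het:
        # biallelic loci: both parents heterozygous means the same ref/alt pair
        return ParentPattern.BOTH_HET_IDENTICAL
    if f_het != m_het:
        return ParentPattern.ONE_PARENT_HET
    if f_hom and m_hom:
        return ParentPattern.PARENTS_HOM_DIFFERENT if f != m else ParentPattern.PARENTS_HOM_SAME
    return ParentPattern.OTHER


def parent_patterns(matrix: GenotypeMatrix) -> list:
    return [
        _pattern_from_codes(int(f), int(m))
        for f, m in zip(matrix.codes[:, 0], matrix.codes[:, 1])
    ]


@dataclass(frozen=True)
class IndividualStats:
    """Genotype composition of one individual over all loci."""

    individual: str
    n_hom: int
    n_het: int
    n_missing: int
    p_hom: float
    p_het: float
    p_missing: float


def per_individual_stats(matrix: GenotypeMatrix) -> tuple:
    """Count HOM/HET/MISSING per individual and summarise across individuals.

    Returns ``(stats, summary)`` where ``stats`` is a list of
    :class:`IndividualStats` (matrix individual order) and ``summary`` maps
    each proportion to its min/max/mean across individuals.
    """
    if matrix.n_loci == 0:
        raise UsageError("per_individual_stats requires at least one locus")
    codes = matrix.codes
    n = matrix.n_loci
    stats = []
    for j, sid in enumerate(matrix.individuals):
        col = codes[:, j]
        n_hom = int(((col == HOM_REF) | (col == HOM_ALT)).sum())
        n_het = int((col == HET).sum())
        n_missing = int((col == MISSING).sum())
        stats.append(
            IndividualStats(sid, n_hom, n_het, n_missing, n_hom / n, n_het / n, n_missing / n)
        )
    summary = {}
    for name in ("p_hom", "p_het", "p_missing"):
        vals = np.array([getattr(s, name) for s in stats])
        summary[name] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
        }
    return stats, summary


def classification_summary(
    matrix: GenotypeMatrix, *, identical_requires_complete: bool = True
) -> dict:
    """Counts and fractions of locus classes and parent patterns.

    The two top-level class fractions (het_any, uniform_homozygous) sum
    to 1.  Both the strict and relaxed identical-heterozygous counts are
    reported; ``identical_requires_complete`` selects which one populates
    the headline ``n_identical_het_all`` field.
    """
    table = classify_matrix(matrix, identical_requires_complete=True)
    relaxed = classify_matrix(matrix, identical_requires_complete=False)
    n = len(table)
    n_het_any = int(table["het_any"].sum())
    n_ident_strict = int(table["identical_het_all"].sum())
    n_ident_relaxed = int(relaxed["identical_het_all"].sum())
    patterns = parent_patterns(matrix)
    pattern_counts = {p.value: 0 for p in ParentPattern}
    for p in patterns:
        pattern_counts[p.value] += 1
    n_ident = n_ident_strict if identical_requires_complete else n_ident_relaxed
    return {
        "n_loci": n,
        "n_het_any": n_het_any,
        "n_uniform_homozygous": n - n_het_any,
        "n_identical_het_all": n_ident,
        "n_identical_het_all_strict": n_ident_strict,
        "n_identical_het_all_relaxed": n_ident_relaxed,
        "frac_het_any": n_het_any / n if n else 0.0,
        "frac_uniform_homozygous": (n - n_het_any) / n if n else 0.0,
        "frac_identical_het_all": n_ident / n if n else 0.0,
        "parent_pattern_counts": pattern_counts,
    }


@dataclass(frozen=True)
class SegregationResult:
    """1:1 segregation test at a locus with homozygous, differing parents.

    Offspring homozygous for the female-parent allele vs the male-parent
    allele form the two cells of a Pearson chi-square goodness-of-fit test
    (df=1, no continuity correction); heterozygous and missing offspring
    are excluded from the test but reported.
    """

    locus_id: str
    n_allele_female: int
    n_allele_male: int
    n_het_offspring: int
    n_missing_offspring: int
    chi2: float
    p_value: float
    consistent_1_1: bool | None
    untestable: bool = False


def segregation_test(
    locus_index: int, matrix: GenotypeMatrix, alpha: float = 0.05
) -> SegregationResult:
    """Test 1:1 offspring segregation of the two parental alleles."""
    pattern = parent_pattern(locus_index, matrix)
    if pattern is not ParentPattern.PARENTS_HOM_DIFFERENT:
        raise UsageError(
            f"segregation_test requires PARENTS_HOM_DIFFERENT, got {pattern.value} "
            f"at {matrix.loci[locus_index].id}"
        )
    f_code, m_code = int(matrix.codes[locus_index, 0]), int(matrix.codes[locus_index, 1])
    off = matrix.codes[locus_index, 2:]
    n_f = int((off == f_code).sum())
    n_m = int((off == m_code).sum())
    n_het = int((off == HET).sum())
    n_missing = int((off == MISSING).sum())
    locus_id = matrix.loci[locus_index].id
    total = n_f + n_m
    if total == 0:
        return SegregationResult(
            locus_id, 0, 0, n_het, n_missing, float("nan"), float("nan"), None, untestable=True
        )
    expected = total / 2.0
    chi2 = (n_f - expected) ** 2 / expected + (n_m - expected) ** 2 / expected
    p = float(chi2_dist.sf(chi2, df=1))
    return SegregationResult(locus_id, n_f, n_m, n_het, n_missing, float(chi2), p, p >= alpha)


_ROUND2 = Decimal("0.01")


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(_ROUND2, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class AnnotationTally:
    """Per-class counts and percentages of a per-sequence annotation table."""

    counts: dict
    percentages: dict
    total: int


def summarize_annotation(table: pd.DataFrame) -> AnnotationTally:
    """Tally per-sequence species annotations by class.

    ``table`` needs columns ``sequence_id``, ``species`` and ``class``
    (one row per query sequence; unannotated sequences carry class
    "Unknown").  Percentages are of the grand total, rounded half-up to
    two decimals.  Class labels are taken as given and not re-curated.
    """
    required = {"sequence_id", "species", "class"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise UsageError(f"annotation table missing columns {sorted(missing_cols)}")
    total = len(table)
    if total == 0:
        warnings.warn("empty annotation table: all tallies zero", stacklevel=2)
        return AnnotationTally({}, {}, 0)
    counts = table["class"].value_counts().to_dict()
    counts = {str(k): int(v) for k, v in counts.items()}
    percentages = {k: _pct(v, total) for k, v in counts.items()}
    return AnnotationTally(counts, percentages, total)


def expand_annotation_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand a (class, species, count) summary into per-sequence rows.

    Published annotation results are often reported as per-species counts
    rather than per-sequence rows; this reverses that aggregation,
    inventing sequential sequence ids, so :func:`summarize_annotation`
    can be applied to them.
    """
    required = {"class", "species", "count"}
    missing_cols = required - set(counts.columns)
    if missing_cols:
        raise UsageError(f"count table missing columns {sorted(missing_cols)}")
    rows = []
    k = 0
    for rec in counts.to_dict("records"):
        for _ in range(int(rec["count"])):
            k += 1
            rows.append((f"seq{k:05d}", rec["species"], rec["class"]))
    return pd.DataFrame(rows, columns=["sequence_id", "species", "class"])
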
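"""Genotype- and allele-level case-control association for biallelic SNPs.

Orientation is fixed throughout: obese subjects are the cases, lean subjects
the controls, and the reference category is the major-allele homozygote
(genotype level) or the major allele (allele level).  An odds ratio above 1
means the index category is enriched among obese women.

The odds ratio is the cross-product (a*d)/(b*c); its 95% confidence interval
uses Woolf's logit method exp(ln OR +/- z*sqrt(1/a+1/b+1/c+1/d)) with
z = 1.96.  P-values come from the uncorrected Pearson chi-square statistic
N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on 1 df, or from Fisher's exact test
when any expected cell count falls below a threshold (default 5).  No Yates
continuity correction is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction

from scipy import stats

from .cohort import GenotypeCountTable
from .errors import ValidationError

WOOLF_Z = 1.96               # 95% two-sided normal quantile as conventionally rounded
FISHER_EXPECTED_THRESHOLD = 5.0


@dataclass(frozen=True)
class TwoByTwoTable:
    """Case-control 2x2 table.

    a: cases with the index category,  b: controls with the index category,
    c: cases with the reference,       d: controls with the reference.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 cells must be non-negative")
        if self.total < 1:
            raise ValidationError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def swapped(self) -> "TwoByTwoTable":
        """Index and reference categories exchanged."""
        return TwoByTwoTable(self.c, self.d, self.a, self.b)

    def haldane_corrected(self) -> "TwoByTwoTable2F":
        return TwoByTwoTable2F(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def min_expected(self) -> float:
        """Smallest expected cell count under independence of the margins."""
        n = self.total
        rows = (self.a + self.b, self.c + self.d)
        cols = (self.a + self.c, self.b + self.d)
        return min(r * c / n for r in rows for c in cols)


@dataclass(frozen=True)
class TwoByTwoTable2F:
    """Real-valued 2x2 (after Haldane-Anscombe +0.5 correction)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def cells(self):
        return (self.a, self.b, self.c, self.d)


@dataclass
class AssociationResult:
    snp_id: str
    level: str                # 'genotype' | 'allele'
    index_category: str
    reference_category: str
    odds_ratio: float | None  # None when undefined (zero cell, no correction)
    ci_low: float | None
    ci_high: float | None
    p_value: float
    test_used: str            # 'pearson_chi2' | 'fisher_exact'
    correction_applied: bool = False
    table: TwoByTwoTable | None = None


def odds_ratio(t: TwoByTwoTable, haldane: bool = False) -> float | None:
    """Cross-product odds ratio (a*d)/(b*c); exact rational arithmetic first.

    Returns None (undefined) when b*c == 0 and the Haldane-Anscombe
    correction is disabled; with ``haldane=True`` 0.5 is added to every cell.
    """
    if haldane:
        a, b, c, d = t.haldane_corrected().cells
        return (a * d) / (b * c)
    if t.b * t.c == 0:
        return None
    return float(Fraction(t.a * t.d, t.b * t.c))


def woolf_ci(
    t: TwoByTwoTable, confidence: float = 0.95, haldane: bool = False
) -> tuple[float, float] | None:
    """Woolf (logit) confidence interval for the odds ratio.

    Requires all four cells positive (after the optional correction);
    otherwise returns None.  ``confidence`` other than 0.95 uses the exact
    normal quantile; at 0.95 the conventional z = 1.96 is used.
    """
    cells = t.haldane_corrected().cells if haldane else t.cells
    if min(cells) <= 0:
        return None
    a, b, c, d = cells
    z = WOOLF_Z if confidence == 0.95 else float(stats.norm.ppf(0.5 + confidence / 2))
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def pearson_chi2_2x2(t: TwoByTwoTable) -> tuple[float, float, bool]:
    """Uncorrected Pearson chi-square on a 2x2 -> (chi2, p, degenerate).

    A zero margin makes the statistic undefined; that case is reported as
    chi2 = 0, p = 1 with the degenerate flag set.
    """
    a, b, c, d = t.cells
    n = t.total
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0, True
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), False


def fisher_exact_2x2(t: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of all
    tables with the observed margins no more probable than the observed one.
    Degenerate margins give p = 1."""
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def _test_2x2(t: TwoByTwoTable, fisher_threshold: float) -> tuple[float, str]:
    if t.min_expected() < fisher_threshold:
        return fisher_exact_2x2(t), "fisher_exact"
    chi2, p, degenerate = pearson_chi2_2x2(t)
    if degenerate:
        return 1.0, "pearson_chi2"
    return p, "pearson_chi2"


def _associate(
    snp_id: str,
    level: str,
    index_category: str,
    reference_category: str,
    t: TwoByTwoTable,
    fisher_threshold: float,
    haldane: bool,
) -> AssociationResult:
    or_ = odds_ratio(t, haldane=haldane)
    ci = woolf_ci(t, haldane=haldane)
    p, test = _test_2x2(t, fisher_threshold)
    return AssociationResult(
        snp_id=snp_id,
        level=level,
        index_category=index_category,
        reference_category=reference_category,
        odds_ratio=or_,
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
        p_value=p,
        test_used=test,
        correction_applied=haldane,
        table=t,
    )


def genotype_association(
    lean_counts: GenotypeCountTable,
    obese_counts: GenotypeCountTable,
    fisher_threshold: float = FISHER_EXPECTED_THRESHOLD,
    haldane: bool = False,
) -> list[AssociationResult]:
    """Association results for one SNP: het and minor-hom vs the major-hom
    reference, plus the allele-level minor-vs-major comparison.

    Fisher's exact test replaces the Pearson chi-square whenever any expected
    cell of the 2x2 falls below ``fisher_threshold``.
    """
    if lean_counts.snp_id != obese_counts.snp_id:
        raise ValidationError(
            f"count tables are for different SNPs: "
            f"{lean_counts.snp_id!r} vs {obese_counts.snp_id!r}"
        )
    if lean_counts.n == 0 or obese_counts.n == 0:
        raise ValidationError(f"{lean_counts.snp_id}: empty group")
    snp_id = lean_counts.snp_id
    major, minor = lean_counts.major_allele, lean_counts.minor_allele
    maj_hom, het, min_hom = major + major, major + minor, minor + minor

    results = []
    for index_cat, obese_n, lean_n in (
        (het, obese_counts.n_het, lean_counts.n_het),
        (min_hom, obese_counts.n_minor_hom, lean_counts.n_minor_hom),
    ):
        t = TwoByTwoTable(
            a=obese_n,
            b=lean_n,
            c=obese_counts.n_major_hom,
            d=lean_counts.n_major_hom,
        )
        results.append(
            _associate(snp_id, "genotype", index_cat, maj_hom, t, fisher_threshold, haldane)
        )
    lean_major, lean_minor = lean_counts.allele_counts
    obese_major, obese_minor = obese_counts.allele_counts
    t_allele = TwoByTwoTable(a=obese_minor, b=lean_minor, c=obese_major, d=lean_major)
    results.append(
        _associate(snp_id, "allele", minor, major, t_allele, fisher_threshold, haldane)
    )
    return results
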
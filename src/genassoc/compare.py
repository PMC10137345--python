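"""Nonparametric phenotype comparisons across groups and joint-genotype strata.

The workhorse is the two-sided Mann-Whitney U test: exact enumeration for
small untied samples (both sizes <= 8), otherwise the normal approximation
with tie-corrected variance and no continuity correction.  Subjects are
stratified by their joint genotype at two loci ("co-existence" analysis) and
continuous traits are summarised as mean +/- SD per stratum; strata smaller
than the minimum testable size (default 5) are summarised but flagged and
excluded from testing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix
from .errors import ValidationError

MIN_STRATUM_N = 5
EXACT_MAX_N = 8


@dataclass
class ComparisonResult:
    phenotype: str | None
    stratum_pair: tuple[str, str] | None
    n1: int
    n2: int
    u: float            # U statistic for the first sample
    z: float            # tie-corrected normal approximation (first sample larger -> z > 0)
    p_value: float
    method: str         # 'exact' | 'normal_approx'


@dataclass
class JointGenotypeStratum:
    """Samples carrying a stated genotype at each of two SNPs."""

    snp_a: str
    genotype_a: str
    snp_b: str
    genotype_b: str
    sample_ids: list[str]

    @property
    def label(self) -> str:
        return f"{self.snp_a}:{self.genotype_a}|{self.snp_b}:{self.genotype_b}"

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class StratumSummary:
    stratum: str
    phenotype: str
    n: int
    mean: float | None
    sd: float | None    # reported only when n >= 2
    low_n: bool         # below the minimum testable size


def _tie_corrected_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U1, z) from midranks with tie-corrected variance; z = 0 if variance 0."""
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    z = (u1 - mu) / math.sqrt(var) if var > 0 else 0.0
    return float(u1), float(z)


def mann_whitney_u(x, y, phenotype: str | None = None,
                   stratum_pair: tuple[str, str] | None = None) -> ComparisonResult:
    """Two-sided Mann-Whitney U test of x vs y.

    U is computed from midranks (U1 + U2 = n1*n2).  The p-value is exact by
    enumeration when both samples have <= 8 observations and the pooled data
    are untied; otherwise the tie-corrected normal approximation is used,
    without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney_u: empty sample")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties
    u1, z = _tie_corrected_z(x, y)
    if exact:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p, method = float(res.pvalue), "exact"
    else:
        if z == 0.0:
            p = 1.0
        else:
            p = float(2 * stats.norm.sf(abs(z)))
        method = "normal_approx"
    return ComparisonResult(
        phenotype=phenotype,
        stratum_pair=stratum_pair,
        n1=len(x),
        n2=len(y),
        u=u1,
        z=z,
        p_value=min(p, 1.0),
        method=method,
    )


def stratify_by_joint_genotype(
    gm: GenotypeMatrix, snp_a: str, snp_b: str
) -> list[JointGenotypeStratum]:
    """Partition samples by their joint genotype at two SNPs.

    One stratum per observed genotype pair; samples missing at either SNP are
    in no stratum, so the strata are disjoint and cover exactly the complete
    cases.  Strata are ordered by canonical genotype order (major-hom, het,
    minor-hom) at each locus.
    """
    calls_a, calls_b = gm.calls(snp_a), gm.calls(snp_b)
    order_a = {g: i for i, g in enumerate(gm.genotype_labels(snp_a))}
    order_b = {g: i for i, g in enumerate(gm.genotype_labels(snp_b))}
    complete = calls_a.notna() & calls_b.notna()
    strata = []
    observed = {
        (a, b)
        for a, b in zip(calls_a[complete], calls_b[complete])
    }
    for geno_a, geno_b in sorted(observed, key=lambda ab: (order_a[ab[0]], order_b[ab[1]])):
        mask = complete & (calls_a == geno_a) & (calls_b == geno_b)
        strata.append(
            JointGenotypeStratum(
                snp_a=snp_a,
                genotype_a=geno_a,
                snp_b=snp_b,
                genotype_b=geno_b,
                sample_ids=list(calls_a.index[mask]),
            )
        )
    return strata


def compare_phenotypes_across_strata(
    strata: list[JointGenotypeStratum],
    phenotypes: pd.DataFrame,
    phenotype_names: list[str],
    pairs: list[tuple[str, str]] | None = None,
    min_n: int = MIN_STRATUM_N,
) -> tuple[list[StratumSummary], list[ComparisonResult]]:
    """Summaries (mean +/- SD) per stratum per phenotype, plus Mann-Whitney
    comparisons between stratum pairs.

    ``pairs`` selects the stratum labels to test (default: every unordered
    pair of strata with n >= min_n).  Strata below ``min_n`` are summarised
    with a low-n flag and never tested.  With fewer than two testable strata
    the comparison list is empty; no exception is raised.
    """
    by_label = {s.label: s for s in strata}
    summaries = []
    for s in strata:
        for phen in phenotype_names:
            values = phenotypes.loc[s.sample_ids, phen].dropna()
            n = len(values)
            summaries.append(
                StratumSummary(
                    stratum=s.label,
                    phenotype=phen,
                    n=n,
                    mean=float(values.mean()) if n >= 1 else None,
                    sd=float(values.std(ddof=1)) if n >= 2 else None,
                    low_n=s.n < min_n,
                )
            )
    testable = [s.label for s in strata if s.n >= min_n]
    if pairs is None:
        pairs = list(itertools.combinations(testable, 2))
    comparisons = []
    for label1, label2 in pairs:
        s1, s2 = by_label[label1], by_label[label2]
        if s1.n < min_n or s2.n < min_n:
            continue
        for phen in phenotype_names:
            x = phenotypes.loc[s1.sample_ids, phen].dropna()
            y = phenotypes.loc[s2.sample_ids, phen].dropna()
            if len(x) == 0 or len(y) == 0:
                continue
            comparisons.append(
                mann_whitney_u(x, y, phenotype=phen, stratum_pair=(label1, label2))
            )
    return summaries, comparisons


def whr_by_bmi_class_table(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    snp_fam: str,
    snp_ppar: str,
    min_n: int = MIN_STRATUM_N,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fat-distribution table: WHR by BMI class x FAM13A genotype x PPAR-gamma2
    C1431 genotype row, with a Mann-Whitney p between the het (C1431T) and
    major-hom (C1431C) rows of each cell.

    Returns a tidy frame with one row per (bmi_class, fam_genotype,
    ppar_genotype): n, WHR mean/SD, and on the het row the p-value of the
    het-vs-major-hom comparison plus a ``label`` column rendering 'ns' when
    p >= alpha and '-' when a cell is empty or too small to test.
    """
    if "group" not in phenotypes.columns or "WHR" not in phenotypes.columns:
        raise ValidationError("phenotype table must carry 'group' and 'WHR' columns")
    fam_labels = gm.genotype_labels(snp_fam)
    ppar_maj_hom, ppar_het, _ = gm.genotype_labels(snp_ppar)
    calls_fam, calls_ppar = gm.calls(snp_fam), gm.calls(snp_ppar)
    rows = []
    for bmi_class in ("lean", "obese"):
        in_class = phenotypes["group"] == bmi_class
        for fam_geno in fam_labels:
            cell_values = {}
            for ppar_geno in gm.genotype_labels(snp_ppar):
                mask = (
                    in_class
                    & (calls_fam.reindex(phenotypes.index) == fam_geno)
                    & (calls_ppar.reindex(phenotypes.index) == ppar_geno)
                )
                whr = phenotypes.loc[mask, "WHR"].dropna()
                cell_values[ppar_geno] = whr
                rows.append(
                    {
                        "bmi_class": bmi_class,
                        "fam_snp": snp_fam,
                        "fam_genotype": fam_geno,
                        "ppar_genotype": ppar_geno,
                        "n": len(whr),
                        "whr_mean": float(whr.mean()) if len(whr) else np.nan,
                        "whr_sd": float(whr.std(ddof=1)) if len(whr) >= 2 else np.nan,
                        "p_value": np.nan,
                        "label": "-" if len(whr) == 0 else "",
                    }
                )
            het, maj = cell_values[ppar_het], cell_values[ppar_maj_hom]
            if len(het) >= min_n and len(maj) >= min_n:
                p = mann_whitney_u(het, maj).p_value
                for row in rows:
                    if (
                        row["bmi_class"] == bmi_class
                        and row["fam_genotype"] == fam_geno
                        and row["ppar_genotype"] == ppar_het
                    ):
                        row["p_value"] = p
                        row["label"] = "ns" if p >= alpha else f"p={p:.4f}"
    return pd.DataFrame(rows)
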
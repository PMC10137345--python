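"""Hardy-Weinberg equilibrium chi-square test per SNP per group.

For a biallelic SNP with minor allele frequency q estimated from the
observed genotype counts, the expected genotype counts under random mating
are n*((1-q)^2, 2q(1-q), q^2).  The goodness-of-fit statistic
sum((obs-exp)^2/exp) is referred to a chi-square distribution with 1 degree
of freedom (3 cells - 1 - 1 estimated allele frequency).  No continuity
correction is applied and no exact test is offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import GenotypeCountTable
from .errors import ValidationError

DEFAULT_ALPHA = 0.05


@dataclass
class HweResult:
    snp_id: str
    group: str
    q: float                              # minor allele frequency
    expected_counts: tuple[float, float, float]
    chi2: float
    p_value: float
    in_equilibrium: bool
    alpha: float = DEFAULT_ALPHA
    degenerate: bool = False              # expected cell 0 with nonzero observed


def allele_frequency(counts: GenotypeCountTable) -> float:
    """Minor allele frequency (2*hom_minor + het) / (2*n)."""
    if counts.n == 0:
        raise ValidationError(f"{counts.snp_id}/{counts.group}: zero non-missing samples")
    return (2 * counts.n_minor_hom + counts.n_het) / (2 * counts.n)


def hwe_chi2_test(counts: GenotypeCountTable, alpha: float = DEFAULT_ALPHA) -> HweResult:
    """Chi-square goodness-of-fit test of HWE for one SNP in one group.

    Degenerate case: if an expected cell is exactly 0 while the observed cell
    is nonzero (impossible under the fitted frequency), the statistic is
    reported as +inf with p = 0 and the result flagged, rather than raising.
    """
    q = allele_frequency(counts)
    n = counts.n
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q]) * n
    observed = np.array(counts.genotype_counts, dtype=float)
    degenerate = bool(np.any((expected == 0) & (observed > 0)))
    if degenerate:
        chi2 = float("inf")
        p = 0.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
        chi2 = float(terms.sum())
        p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        snp_id=counts.snp_id,
        group=counts.group,
        q=q,
        expected_counts=tuple(expected),
        chi2=chi2,
        p_value=p,
        in_equilibrium=bool(p >= alpha),
        alpha=alpha,
        degenerate=degenerate,
    )
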
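"""Combined-Z multiphenotype omnibus association test with Holm correction.

Each (SNP, phenotype) label yields a signed univariate Z: the tie-corrected
normal transform of the Mann-Whitney statistic comparing the phenotype
between obese (cases) and lean (controls) women among carriers of that
SNP's minor allele; positive Z means the trait runs higher in the obese
group.  Under the global null the Z vector is treated as multivariate
normal with mean 0 and a covariance estimated empirically — by default the
sample covariance of the Z vector across bootstrap resamples of subjects
(drawn with replacement within each group).  Two combined statistics are
offered:

``sum`` (O'Brien-type, default)
    T = (1'z) / sqrt(1' Sigma 1), two-sided standard-normal p.  Sensitive to
    effects that share a direction.
``quadratic`` (Wald-type)
    Q = z' Sigma^-1 z, chi-square p with df = rank(Sigma).  Direction-
    agnostic.

Holm-Bonferroni step-down adjustment is provided for the family of all
per-label tests in a run.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compare import _tie_corrected_z
from .cohort import GenotypeMatrix
from .errors import ValidationError

MIN_SIDE_N = 5  # smallest per-side sample admitted to a univariate comparison


@dataclass
class ZVector:
    labels: list[tuple[str, str]]          # (snp_id, phenotype)
    z: np.ndarray
    source: list[str] = field(default_factory=list)
    excluded: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.z) != len(self.labels):
            raise ValidationError("ZVector: labels and z lengths differ")
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("ZVector: non-finite entries")


@dataclass
class ZCovariance:
    matrix: np.ndarray                     # covariance of the Z vector
    correlation: np.ndarray                # unit-diagonal scaling of `matrix`
    estimator: str                         # 'bootstrap' | 'score_contributions'
    n_resamples: int = 0
    n_redrawn: int = 0


@dataclass
class OmnibusResult:
    statistic: float
    p_value: float
    method: str                            # 'sum' | 'quadratic'
    df: int | None
    null_variance: float | None
    z: ZVector
    cov: ZCovariance | None
    rank_deficient: bool = False


@dataclass
class HolmResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    alpha: float


def univariate_z(x, y) -> float:
    """Signed Mann-Whitney Z for cases ``x`` vs controls ``y``.

    Tie-corrected normal transform of U; positive when x is stochastically
    larger.  Reversing the roles of x and y negates the value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("univariate_z: empty sample")
    _, z = _tie_corrected_z(x, y)
    return z


def _comparison_arrays(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    snp_id: str,
    phenotype: str,
    case_ids: np.ndarray,
    control_ids: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype values among minor-allele carriers, split case/control."""
    calls = gm.calls(snp_id)
    _, het, min_hom = gm.genotype_labels(snp_id)
    carrier = calls.isin([het, min_hom])
    carriers = set(calls.index[carrier])
    x = phenotypes.loc[[s for s in case_ids if s in carriers], phenotype].dropna()
    y = phenotypes.loc[[s for s in control_ids if s in carriers], phenotype].dropna()
    return x.to_numpy(), y.to_numpy()


def _group_ids(phenotypes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "group" not in phenotypes.columns:
        raise ValidationError("phenotype table must carry a 'group' column")
    grp = phenotypes["group"]
    return (
        phenotypes.index[grp == "obese"].to_numpy(),
        phenotypes.index[grp == "lean"].to_numpy(),
    )


def z_vector(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    snps: list[str] | None = None,
    phenotype_names: list[str] | None = None,
    min_n: int = MIN_SIDE_N,
) -> ZVector:
    """Build the full (SNP, phenotype) Z vector for a cohort.

    Comparisons with fewer than ``min_n`` subjects on either side are
    excluded and listed with a reason in ``ZVector.excluded``.
    """
    snps = snps if snps is not None else gm.snp_ids
    if phenotype_names is None:
        phenotype_names = [
            c for c in phenotypes.columns if c not in ("group",) and
            pd.api.types.is_numeric_dtype(phenotypes[c])
        ]
    case_ids, control_ids = _group_ids(phenotypes)
    labels, zs, sources, excluded = [], [], [], []
    for snp_id, phen in itertools.product(snps, phenotype_names):
        x, y = _comparison_arrays(gm, phenotypes, snp_id, phen, case_ids, control_ids)
        if len(x) < min_n or len(y) < min_n:
            excluded.append(
                ((snp_id, phen), f"undersized comparison: {len(x)} cases, {len(y)} controls")
            )
            continue
        labels.append((snp_id, phen))
        zs.append(univariate_z(x, y))
        sources.append("mann_whitney_carriers")
    return ZVector(labels=labels, z=np.array(zs), source=sources, excluded=excluded)


def estimate_z_covariance(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    labels: list[tuple[str, str]],
    n_resamples: int = 1000,
    seed: int | None = None,
    min_n: int = 2,
) -> ZCovariance:
    """Bootstrap covariance of the Z vector.

    Subjects are resampled with replacement within each group; the full Z
    vector is recomputed per resample and the sample covariance across
    resamples returned.  A resample leaving any label with fewer than
    ``min_n`` subjects on a side is redrawn (count reported).
    """
    if n_resamples < 100:
        raise ValidationError("n_resamples must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    case_ids, control_ids = _group_ids(phenotypes)

    # precompute per-label carrier values so each bootstrap draw is O(n) lookups
    per_label: list[tuple[np.ndarray, np.ndarray]] = []
    for snp_id, phen in labels:
        calls = gm.calls(snp_id)
        _, het, min_hom = gm.genotype_labels(snp_id)
        carriers = set(calls.index[calls.isin([het, min_hom])])
        case_vals = phenotypes[phen].reindex(case_ids)
        ctrl_vals = phenotypes[phen].reindex(control_ids)
        case_mask = np.array([s in carriers for s in case_ids]) & case_vals.notna().to_numpy()
        ctrl_mask = np.array([s in carriers for s in control_ids]) & ctrl_vals.notna().to_numpy()
        per_label.append(
            (
                np.where(case_mask, case_vals.to_numpy(), np.nan),
                np.where(ctrl_mask, ctrl_vals.to_numpy(), np.nan),
            )
        )

    draws = np.empty((n_resamples, len(labels)))
    n_redrawn = 0
    b = 0
    attempts = 0
    while b < n_resamples:
        attempts += 1
        if attempts > 50 * n_resamples:
            raise ValidationError(
                "too many degenerate bootstrap resamples; groups too small"
            )
        case_idx = rng.integers(0, len(case_ids), len(case_ids))
        ctrl_idx = rng.integers(0, len(control_ids), len(control_ids))
        row = np.empty(len(labels))
        ok = True
        for j, (case_vals, ctrl_vals) in enumerate(per_label):
            x = case_vals[case_idx]
            y = ctrl_vals[ctrl_idx]
            x = x[~np.isnan(x)]
            y = y[~np.isnan(y)]
            if len(x) < min_n or len(y) < min_n:
                ok = False
                break
            row[j] = univariate_z(x, y)
        if not ok:
            n_redrawn += 1
            continue
        draws[b] = row
        b += 1
    cov = np.cov(draws, rowvar=False)
    cov = np.atleast_2d(cov)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return ZCovariance(
        matrix=cov,
        correlation=corr,
        estimator="bootstrap",
        n_resamples=n_resamples,
        n_redrawn=n_redrawn,
    )


def score_contribution_covariance(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    labels: list[tuple[str, str]],
) -> ZCovariance:
    """Plug-in covariance from per-subject rank score contributions.

    Non-default, cheaper alternative to the bootstrap: each subject's
    centred, group-signed midrank contribution to each label's Z is stacked
    into a subjects x labels score matrix (zero where a subject is outside a
    comparison) and the correlation of its columns taken as the Z
    correlation.  The diagonal is unit by construction.
    """
    case_ids, control_ids = _group_ids(phenotypes)
    all_ids = list(case_ids) + list(control_ids)
    signs = np.array([1.0] * len(case_ids) + [-1.0] * len(control_ids))
    scores = np.zeros((len(all_ids), len(labels)))
    pos = {s: i for i, s in enumerate(all_ids)}
    for j, (snp_id, phen) in enumerate(labels):
        calls = gm.calls(snp_id)
        _, het, min_hom = gm.genotype_labels(snp_id)
        carriers = calls.index[calls.isin([het, min_hom])]
        values = phenotypes[phen].reindex(carriers).dropna()
        ids = [s for s in values.index if s in pos]
        vals = values.reindex(ids).to_numpy()
        ranks = stats.rankdata(vals)
        centred = ranks - ranks.mean()
        norm = math.sqrt((centred**2).sum()) or 1.0
        for s, r in zip(ids, centred / norm):
            scores[pos[s], j] = r * signs[pos[s]]
    cov = np.atleast_2d(np.cov(scores, rowvar=False))
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return ZCovariance(matrix=corr, correlation=corr, estimator="score_contributions")


def _check_cov(matrix: np.ndarray, k: int) -> np.ndarray:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape != (k, k):
        raise ValidationError(f"covariance shape {matrix.shape} does not match k={k}")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValidationError("covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(matrix)
    if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
        raise ValidationError(
            "covariance is not positive semi-definite; increase n_resamples"
        )
    return matrix


def omnibus_test(z: ZVector, cov: ZCovariance | np.ndarray, method: str = "sum") -> OmnibusResult:
    """Combine a Z vector into one omnibus statistic under the MVN null.

    method='sum': T = (1'z)/sqrt(1'Sigma 1), two-sided standard-normal p.
    method='quadratic': Q = z'Sigma^-1 z, chi-square p with df = rank(Sigma)
    (pseudo-inverse with the result flagged when Sigma is rank deficient).
    With k = 1 both reduce exactly to the univariate two-sided p.
    """
    zc = cov if isinstance(cov, ZCovariance) else None
    matrix = _check_cov(cov.matrix if zc else cov, len(z.z))
    if method == "sum":
        null_var = float(matrix.sum())
        if null_var <= 0:
            raise ValidationError("1'Sigma 1 must be positive for the sum method")
        t = float(z.z.sum() / math.sqrt(null_var))
        p = float(2 * stats.norm.sf(abs(t)))
        return OmnibusResult(
            statistic=t, p_value=p, method="sum", df=None,
            null_variance=null_var, z=z, cov=zc,
        )
    if method == "quadratic":
        rank = int(np.linalg.matrix_rank(matrix, hermitian=True))
        if rank == 0:
            raise ValidationError("covariance matrix has rank 0")
        inv = np.linalg.pinv(matrix, hermitian=True)
        q = float(z.z @ inv @ z.z)
        p = float(stats.chi2.sf(q, df=rank))
        return OmnibusResult(
            statistic=q, p_value=p, method="quadratic", df=rank,
            null_variance=None, z=z, cov=zc, rank_deficient=rank < len(z.z),
        )
    raise ValidationError(f"unknown omnibus method {method!r}")


def holm_bonferroni(raw_p, alpha: float = 0.05) -> HolmResult:
    """Holm-Bonferroni step-down adjustment of a p-value family."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.ndim != 1 or len(raw_p) == 0:
        raise ValidationError("raw_p must be a non-empty 1-d vector")
    if np.any((raw_p < 0) | (raw_p > 1)) or not np.all(np.isfinite(raw_p)):
        raise ValidationError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    return HolmResult(raw_p=raw_p, adjusted_p=adjusted, rejected=rejected, alpha=alpha)
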
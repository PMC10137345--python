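"""End-to-end orchestration: simulate/load -> HWE -> association -> co-existence
-> omnibus, with a reproducibility manifest and text-table rendering."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import FISHER_EXPECTED_THRESHOLD, genotype_association
from .cohort import (
    GenotypeMatrix,
    classify_bmi_group,
    count_genotypes,
    derive_indices,
    read_genotype_csv,
    read_phenotype_csv,
    write_genotype_csv,
    write_phenotype_csv,
)
from .compare import MIN_STRATUM_N, compare_phenotypes_across_strata, stratify_by_joint_genotype
from .errors import ValidationError
from .hwe import DEFAULT_ALPHA, hwe_chi2_test
from .omnibus import estimate_z_covariance, holm_bonferroni, omnibus_test, z_vector
from .simulate import SimulationConfig, config_from_dict, config_to_dict, simulate_cohort

logger = logging.getLogger("genassoc")

DEFAULT_COEXIST_PAIRS = [
    ("rs1903003", "rs3856806"),
    ("rs7671167", "rs3856806"),
    ("rs2869967", "rs3856806"),
]
DEFAULT_COEXIST_PHENOTYPES = [
    "BMI", "body_mass", "FBM_pct", "LBM_pct", "BMR", "SBP", "DBP", "WHR",
]


@dataclass
class RunConfig:
    """Pipeline run: either a simulation config or a pair of input CSVs."""

    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    alpha: float = DEFAULT_ALPHA
    fisher_threshold: float = FISHER_EXPECTED_THRESHOLD
    min_stratum_n: int = MIN_STRATUM_N
    omnibus_method: str = "sum"
    n_resamples: int = 1000
    coexist_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COEXIST_PAIRS)
    )
    coexist_phenotypes: list[str] = field(
        default_factory=lambda: list(DEFAULT_COEXIST_PHENOTYPES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.genotypes_path is not None or self.phenotypes_path is not None
        if self.simulation is not None and has_paths:
            raise ValidationError("give either a simulation config or input paths, not both")
        if self.simulation is None and not (self.genotypes_path and self.phenotypes_path):
            raise ValidationError("either a simulation config or both input paths required")
        if self.alpha <= 0 or self.fisher_threshold <= 0 or self.min_stratum_n <= 0:
            raise ValidationError("thresholds must be positive")

    def to_dict(self) -> dict:
        d = {
            "genotypes_path": self.genotypes_path,
            "phenotypes_path": self.phenotypes_path,
            "alpha": self.alpha,
            "fisher_threshold": self.fisher_threshold,
            "min_stratum_n": self.min_stratum_n,
            "omnibus_method": self.omnibus_method,
            "n_resamples": self.n_resamples,
            "coexist_pairs": [list(p) for p in self.coexist_pairs],
            "coexist_phenotypes": list(self.coexist_phenotypes),
            "seed": self.seed,
        }
        if self.simulation is not None:
            d["simulation"] = config_to_dict(self.simulation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = config_from_dict(sim)
        pairs = [tuple(p) for p in d.pop("coexist_pairs", DEFAULT_COEXIST_PAIRS)]
        try:
            return cls(simulation=sim, coexist_pairs=pairs, **d)
        except TypeError as exc:
            raise ValidationError(f"invalid run config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_rows: dict[str, int]
    warnings: list[str]
    artifacts: list[str]

    def to_dict(self) -> dict:
        return vars(self).copy()


def ensure_groups(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Guarantee BMI/WHR and a group column, deriving them when absent."""
    out = phenotypes
    if "BMI" not in out.columns or "WHR" not in out.columns:
        out = derive_indices(out)
    if "group" not in out.columns:
        out = out.copy()
        out["group"] = classify_bmi_group(out["BMI"])
    return out


def hwe_table(gm: GenotypeMatrix, groups: pd.Series, alpha: float = DEFAULT_ALPHA,
              by_group: bool = True) -> pd.DataFrame:
    """HWE chi-square results per SNP (per group when ``by_group``)."""
    rows = []
    for snp_id in gm.snp_ids:
        lean, obese = count_genotypes(gm, groups, snp_id)
        tables = [lean, obese]
        if not by_group:
            pooled = lean
            pooled = type(lean)(
                snp_id=snp_id, group="all",
                n_major_hom=lean.n_major_hom + obese.n_major_hom,
                n_het=lean.n_het + obese.n_het,
                n_minor_hom=lean.n_minor_hom + obese.n_minor_hom,
                n_missing=lean.n_missing + obese.n_missing,
                major_allele=lean.major_allele, minor_allele=lean.minor_allele,
            )
            tables = [pooled]
        for table in tables:
            res = hwe_chi2_test(table, alpha=alpha)
            rows.append(
                {
                    "snp_id": res.snp_id,
                    "group": res.group,
                    "n": table.n,
                    "minor_allele_freq": res.q,
                    "chi2": res.chi2,
                    "p_value": res.p_value,
                    "in_equilibrium": res.in_equilibrium,
                }
            )
    return pd.DataFrame(rows)


def association_table(
    gm: GenotypeMatrix,
    groups: pd.Series,
    fisher_threshold: float = FISHER_EXPECTED_THRESHOLD,
    haldane: bool = False,
) -> pd.DataFrame:
    """Tidy case-control association table across all SNPs.

    One row per genotype/allele category, including the reference rows,
    mirroring the published layout: counts with percentages, OR with Woolf
    CI, p-value and the test used.
    """
    rows = []
    for snp_id in gm.snp_ids:
        lean, obese = count_genotypes(gm, groups, snp_id)
        results = genotype_association(
            lean, obese, fisher_threshold=fisher_threshold, haldane=haldane
        )
        maj_hom, het, min_hom = gm.genotype_labels(snp_id)
        major, minor = gm.alleles[snp_id]

        def count_row(level, category, lean_n, lean_tot, obese_n, obese_tot, res=None):
            return {
                "snp_id": snp_id,
                "level": level,
                "category": category,
                "lean_count": lean_n,
                "lean_pct": 100.0 * lean_n / lean_tot,
                "obese_count": obese_n,
                "obese_pct": 100.0 * obese_n / obese_tot,
                "reference": res is None,
                "odds_ratio": res.odds_ratio if res else 1.0,
                "ci_low": res.ci_low if res else math.nan,
                "ci_high": res.ci_high if res else math.nan,
                "p_value": res.p_value if res else math.nan,
                "test_used": res.test_used if res else "",
            }

        by_cat = {(r.level, r.index_category): r for r in results}
        rows.append(count_row("genotype", maj_hom, lean.n_major_hom, lean.n, obese.n_major_hom, obese.n))
        rows.append(count_row("genotype", het, lean.n_het, lean.n, obese.n_het, obese.n,
                              by_cat[("genotype", het)]))
        rows.append(count_row("genotype", min_hom, lean.n_minor_hom, lean.n, obese.n_minor_hom, obese.n,
                              by_cat[("genotype", min_hom)]))
        lean_major, lean_minor = lean.allele_counts
        obese_major, obese_minor = obese.allele_counts
        rows.append(count_row("allele", major, lean_major, 2 * lean.n, obese_major, 2 * obese.n))
        rows.append(count_row("allele", minor, lean_minor, 2 * lean.n, obese_minor, 2 * obese.n,
                              by_cat[("allele", minor)]))
    return pd.DataFrame(rows)


def format_sigfig(x: float, sig: int = 4) -> str:
    """Round to ``sig`` significant figures keeping trailing zeros."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if x == 0:
        return "0"
    decimals = max(sig - 1 - math.floor(math.log10(abs(x))), 0)
    return f"{round(x, decimals):.{decimals}f}"


def render_table2(table: pd.DataFrame) -> str:
    """Text rendering of an association table: counts with percentages to one
    decimal, OR to 4 significant figures, bracketed CI, reference rows marked."""
    lines = []
    header = f"{'category':<12}{'lean n (%)':<16}{'obese n (%)':<16}{'OR (95% CI)':<28}{'p':<10}{'test'}"
    for snp_id, block in table.groupby("snp_id", sort=False):
        lines.append(f"== {snp_id} ==")
        for level in ("genotype", "allele"):
            sub = block[block["level"] == level]
            if sub.empty:
                continue
            lines.append(level.capitalize() + "s")
            lines.append(header)
            for _, row in sub.iterrows():
                lean = f"{row.lean_count} ({row.lean_pct:.1f})"
                obese = f"{row.obese_count} ({row.obese_pct:.1f})"
                if row.reference:
                    or_ci, p = "1 (ref)", ""
                elif row.odds_ratio is None or (
                    isinstance(row.odds_ratio, float) and math.isnan(row.odds_ratio)
                ):
                    or_ci, p = "undefined", f"{row.p_value:.4f}"
                else:
                    ci = (
                        f" [{format_sigfig(row.ci_low)}-{format_sigfig(row.ci_high)}]"
                        if not math.isnan(row.ci_low)
                        else ""
                    )
                    or_ci = f"{format_sigfig(row.odds_ratio)}{ci}"
                    p = f"{row.p_value:.4f}"
                lines.append(
                    f"{row.category:<12}{lean:<16}{obese:<16}{or_ci:<28}{p:<10}{row.test_used}"
                )
        lines.append("")
    return "\n".join(lines)


def coexistence_table(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    pairs: list[tuple[str, str]],
    phenotype_names: list[str],
    min_n: int = MIN_STRATUM_N,
) -> pd.DataFrame:
    """Long-format summaries and pairwise tests for joint-genotype strata."""
    rows = []
    for snp_a, snp_b in pairs:
        strata = stratify_by_joint_genotype(gm, snp_a, snp_b)
        summaries, comparisons = compare_phenotypes_across_strata(
            strata, phenotypes, phenotype_names, min_n=min_n
        )
        for s in summaries:
            rows.append(
                {
                    "record": "summary",
                    "snp_pair": f"{snp_a}|{snp_b}",
                    "stratum": s.stratum,
                    "stratum_b": "",
                    "phenotype": s.phenotype,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "u": math.nan,
                    "p_value": math.nan,
                    "method": "",
                    "low_n": s.low_n,
                }
            )
        for c in comparisons:
            rows.append(
                {
                    "record": "comparison",
                    "snp_pair": f"{snp_a}|{snp_b}",
                    "stratum": c.stratum_pair[0],
                    "stratum_b": c.stratum_pair[1],
                    "phenotype": c.phenotype,
                    "n": c.n1 + c.n2,
                    "mean": math.nan,
                    "sd": math.nan,
                    "u": c.u,
                    "p_value": c.p_value,
                    "method": c.method,
                    "low_n": False,
                }
            )
    return pd.DataFrame(rows)


def omnibus_report(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    method: str = "sum",
    n_resamples: int = 1000,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    phenotype_names: list[str] | None = None,
) -> dict:
    """Full omnibus analysis as a JSON-serialisable dict."""
    zvec = z_vector(gm, phenotypes, phenotype_names=phenotype_names)
    if len(zvec.z) == 0:
        raise ValidationError("no (SNP, phenotype) comparison met the size threshold")
    cov = estimate_z_covariance(
        gm, phenotypes, zvec.labels, n_resamples=n_resamples, seed=seed
    )
    result = omnibus_test(zvec, cov, method=method)
    raw_p = [float(2 * _norm_sf_abs(z)) for z in zvec.z]
    holm = holm_bonferroni(raw_p, alpha=alpha)
    return {
        "method": result.method,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "df": result.df,
        "n_resamples": cov.n_resamples,
        "n_redrawn_resamples": cov.n_redrawn,
        "seed": seed,
        "labels": [list(lbl) for lbl in zvec.labels],
        "z": [float(z) for z in zvec.z],
        "raw_p": [float(p) for p in holm.raw_p],
        "holm_adjusted_p": [float(p) for p in holm.adjusted_p],
        "rejected": [bool(r) for r in holm.rejected],
        "excluded": [[list(lbl), reason] for lbl, reason in zvec.excluded],
    }


def _norm_sf_abs(z: float) -> float:
    from scipy import stats

    return float(stats.norm.sf(abs(z)))


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> RunManifest:
    """Execute simulate/load -> HWE -> association -> co-existence -> omnibus.

    Each stage's output is written before the next starts.  Re-running with
    an identical config and ``force=False`` returns the stored manifest
    without recomputing.  On a stage failure a FAILED marker naming the
    stage is left beside the partial outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    cfg_hash = config.config_hash()
    if manifest_path.exists() and not force:
        stored = json.loads(manifest_path.read_text())
        if stored.get("config_hash") == cfg_hash:
            logger.info("unchanged config %s; skipping recompute", cfg_hash[:12])
            return RunManifest(**stored)

    stage_rows: dict[str, int] = {}
    warnings: list[str] = []
    artifacts: list[str] = []
    stage = "load"
    try:
        if config.simulation is not None:
            stage = "simulate"
            cohort = simulate_cohort(config.simulation)
            gm, phenotypes = cohort.genotypes, cohort.phenotypes
            write_genotype_csv(gm, out_dir / "genotypes.csv")
            write_phenotype_csv(phenotypes, out_dir / "phenotypes.csv")
            artifacts += ["genotypes.csv", "phenotypes.csv"]
        else:
            gm = read_genotype_csv(config.genotypes_path)
            phenotypes = read_phenotype_csv(config.phenotypes_path)
        phenotypes = ensure_groups(phenotypes)
        groups = phenotypes["group"]
        stage_rows[stage] = len(phenotypes)
        logger.info("stage %s: %d samples, %d SNPs", stage, len(phenotypes), len(gm.snp_ids))

        stage = "hwe"
        hwe_df = hwe_table(gm, groups, alpha=config.alpha)
        hwe_df.to_csv(out_dir / "hwe.csv", index=False)
        artifacts.append("hwe.csv")
        stage_rows[stage] = len(hwe_df)
        logger.info("stage hwe: %d rows", len(hwe_df))

        stage = "assoc"
        assoc_df = association_table(gm, groups, fisher_threshold=config.fisher_threshold)
        assoc_df.to_csv(out_dir / "table2.csv", index=False)
        (out_dir / "table2.txt").write_text(render_table2(assoc_df), encoding="utf-8")
        artifacts += ["table2.csv", "table2.txt"]
        stage_rows[stage] = len(assoc_df)
        logger.info("stage assoc: %d rows", len(assoc_df))

        stage = "coexist"
        pairs = [
            (a, b) for a, b in config.coexist_pairs
            if a in gm.snp_ids and b in gm.snp_ids
        ]
        skipped = [p for p in config.coexist_pairs if p not in pairs]
        if skipped:
            warnings.append(f"coexist pairs skipped (SNP absent): {skipped}")
        phen_names = [p for p in config.coexist_phenotypes if p in phenotypes.columns]
        coexist_df = coexistence_table(
            gm, phenotypes, pairs, phen_names, min_n=config.min_stratum_n
        )
        coexist_df.to_csv(out_dir / "coexist.csv", index=False)
        artifacts.append("coexist.csv")
        stage_rows[stage] = len(coexist_df)
        low_n = (
            int(coexist_df.loc[coexist_df["record"] == "summary", "low_n"].sum())
            if len(coexist_df)
            else 0
        )
        if low_n:
            warnings.append(f"{low_n} stratum summaries below min_stratum_n={config.min_stratum_n}")
        logger.info("stage coexist: %d rows", len(coexist_df))

        stage = "omnibus"
        report = omnibus_report(
            gm,
            phenotypes,
            method=config.omnibus_method,
            n_resamples=config.n_resamples,
            seed=config.seed,
            alpha=config.alpha,
        )
        (out_dir / "omnibus.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
        artifacts.append("omnibus.json")
        stage_rows[stage] = len(report["labels"])
        logger.info("stage omnibus: %d labels, p=%.4g", len(report["labels"]), report["p_value"])
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n", encoding="utf-8")
        raise
    (out_dir / "FAILED").unlink(missing_ok=True)

    manifest = RunManifest(
        config_hash=cfg_hash,
        version=__version__,
        seed=config.seed,
        stage_rows=stage_rows,
        warnings=warnings,
        artifacts=artifacts,
    )
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2), encoding="utf-8")
    return manifest
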
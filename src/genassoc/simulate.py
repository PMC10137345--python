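"""Synthetic case-control cohorts with HWE genotypes and Gaussian phenotypes.

The generator emulates a retrospective case-control design: the lean and
obese groups are sampled separately, each SNP's genotypes are drawn from
Hardy-Weinberg proportions at a group-specific minor allele frequency, and
each raw phenotype is drawn from the group's Gaussian.  Optional joint
effects add a fixed shift to one raw trait in the subset of samples that
carry a stated genotype at each of two SNPs, mimicking the co-existence
patterns seen in two-locus stratified analyses.

Defaults reproduce the study conditions: 105 lean and 124 obese
postmenopausal women, the six-SNP panel at the allele frequencies implied by
the published genotype counts, and phenotype means/SDs from the published
group summaries.  SNPs are simulated independently (no linkage
disequilibrium) and phenotypes are drawn independently per trait; only
marginal structure is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .cohort import RAW_PHENOTYPES, GenotypeMatrix, derive_indices
from .errors import ValidationError
from .reference import (
    N_LEAN,
    N_OBESE,
    STUDY_PHENOTYPES,
    STUDY_SNP_PANEL,
    study_minor_allele_frequency,
)

# percentage-of-body-mass traits are truncated to [0, 100]; every other raw
# trait is truncated at 0
_PERCENT_TRAITS = ("FBM_pct", "LBM_pct")


@dataclass
class SnpSpec:
    """One biallelic SNP with group-specific minor allele frequencies."""

    snp_id: str
    gene: str
    major_allele: str
    minor_allele: str
    freq_minor_lean: float
    freq_minor_obese: float

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValidationError(f"{self.snp_id}: major and minor alleles must differ")
        for name in ("freq_minor_lean", "freq_minor_obese"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{self.snp_id}.{name}={f} outside [0, 1]")

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        a, b = self.major_allele, self.minor_allele
        return a + a, a + b, b + b


@dataclass
class PhenotypeSpec:
    """Group-wise Gaussian for one raw phenotype (trait units)."""

    name: str
    mean_lean: float
    sd_lean: float
    mean_obese: float
    sd_obese: float

    def __post_init__(self) -> None:
        if self.name not in RAW_PHENOTYPES:
            raise ValidationError(
                f"unknown phenotype {self.name!r}; must be one of {RAW_PHENOTYPES}"
            )
        if self.sd_lean <= 0 or self.sd_obese <= 0:
            raise ValidationError(f"{self.name}: SDs must be strictly positive")


@dataclass
class JointEffectSpec:
    """Additive shift on one raw trait for carriers of two stated genotypes."""

    snp_a: str
    genotype_a: str
    snp_b: str
    genotype_b: str
    phenotype: str
    shift: float


@dataclass
class SimulationConfig:
    n_lean: int = N_LEAN
    n_obese: int = N_OBESE
    snps: list[SnpSpec] = field(default_factory=list)
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)
    joint_effects: list[JointEffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lean < 1 or self.n_obese < 1:
            raise ValidationError("n_lean and n_obese must be >= 1")
        snp_ids = [s.snp_id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("snp_ids must be unique")
        by_id = {s.snp_id: s for s in self.snps}
        phen_names = {p.name for p in self.phenotypes}
        for eff in self.joint_effects:
            for snp, geno in ((eff.snp_a, eff.genotype_a), (eff.snp_b, eff.genotype_b)):
                if snp not in by_id:
                    raise ValidationError(f"joint effect references unknown SNP {snp!r}")
                if geno not in by_id[snp].genotype_labels:
                    raise ValidationError(
                        f"joint effect genotype {geno!r} not valid for {snp}; "
                        f"expected one of {by_id[snp].genotype_labels}"
                    )
            if eff.phenotype not in phen_names:
                raise ValidationError(
                    f"joint effect references unknown phenotype {eff.phenotype!r}"
                )


class SimulatedCohort(NamedTuple):
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    effect_members: list[list[str]]  # sample ids each joint effect was applied to
    seed: int


def default_config(seed: int = 0, n_lean: int = N_LEAN, n_obese: int = N_OBESE) -> SimulationConfig:
    """Study-default simulation: published panel frequencies and phenotype summaries."""
    snps = [
        SnpSpec(
            snp_id=snp_id,
            gene=gene,
            major_allele=major,
            minor_allele=minor,
            freq_minor_lean=study_minor_allele_frequency(snp_id, "lean"),
            freq_minor_obese=study_minor_allele_frequency(snp_id, "obese"),
        )
        for snp_id, (gene, major, minor, _) in STUDY_SNP_PANEL.items()
    ]
    phenotypes = [
        PhenotypeSpec(name, *params) for name, params in STUDY_PHENOTYPES.items()
    ]
    return SimulationConfig(
        n_lean=n_lean, n_obese=n_obese, snps=snps, phenotypes=phenotypes, seed=seed
    )


def simulate_genotypes_hwe(freq_minor: float, n: int, rng, labels=("AA", "Aa", "aa")):
    """Draw ``n`` genotype labels from Hardy-Weinberg proportions.

    With minor allele frequency q, genotypes are sampled with probabilities
    (1-q)^2, 2q(1-q), q^2 for major-hom, het, minor-hom.
    """
    if not 0.0 <= freq_minor <= 1.0:
        raise ValidationError(f"freq_minor={freq_minor} outside [0, 1]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    q = float(freq_minor)
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    idx = rng.choice(3, size=n, p=probs / probs.sum())
    return np.asarray(labels, dtype=object)[idx]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort: HWE genotypes, Gaussian phenotypes, joint-effect shifts.

    Fully reproducible: one ``numpy.random.default_rng(config.seed)`` drives
    every draw, and the seed is recorded in the returned tuple.  BMI and WHR
    are derived from the simulated raw traits, so a sample's derived BMI may
    occasionally fall outside its group's nominal range; the recorded
    ``group`` column is the sampling group.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_lean + config.n_obese
    sample_ids = [f"L{i:04d}" for i in range(1, config.n_lean + 1)] + [
        f"O{i:04d}" for i in range(1, config.n_obese + 1)
    ]
    group = np.array(["lean"] * config.n_lean + ["obese"] * config.n_obese)

    geno_cols = {}
    for snp in config.snps:
        calls = np.empty(n_total, dtype=object)
        calls[: config.n_lean] = simulate_genotypes_hwe(
            snp.freq_minor_lean, config.n_lean, rng, labels=snp.genotype_labels
        )
        calls[config.n_lean :] = simulate_genotypes_hwe(
            snp.freq_minor_obese, config.n_obese, rng, labels=snp.genotype_labels
        )
        geno_cols[snp.snp_id] = calls
    geno_df = pd.DataFrame(geno_cols, index=pd.Index(sample_ids, name="sample_id"))
    gm = GenotypeMatrix(
        data=geno_df,
        alleles={s.snp_id: (s.major_allele, s.minor_allele) for s in config.snps},
    )

    phen_cols = {}
    for spec in config.phenotypes:
        values = np.empty(n_total)
        values[: config.n_lean] = rng.normal(spec.mean_lean, spec.sd_lean, config.n_lean)
        values[config.n_lean :] = rng.normal(spec.mean_obese, spec.sd_obese, config.n_obese)
        phen_cols[spec.name] = values
    phenotypes = pd.DataFrame(phen_cols, index=geno_df.index)

    effect_members: list[list[str]] = []
    for eff in config.joint_effects:
        mask = (geno_df[eff.snp_a] == eff.genotype_a) & (geno_df[eff.snp_b] == eff.genotype_b)
        phenotypes.loc[mask, eff.phenotype] += eff.shift
        effect_members.append(list(geno_df.index[mask]))

    # truncation after effects so shifts cannot push traits out of range
    for spec in config.phenotypes:
        if spec.name in _PERCENT_TRAITS:
            phenotypes[spec.name] = phenotypes[spec.name].clip(0.0, 100.0)
        else:
            phenotypes[spec.name] = phenotypes[spec.name].clip(lower=0.0)

    if {"height", "body_mass", "waist", "hip"} <= set(phenotypes.columns):
        phenotypes = derive_indices(phenotypes)
    phenotypes["group"] = group
    phenotypes.attrs["seed"] = config.seed
    return SimulatedCohort(gm, phenotypes, effect_members, config.seed)


# ---------------------------------------------------------------------------
# config (de)serialisation


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_lean": config.n_lean,
        "n_obese": config.n_obese,
        "seed": config.seed,
        "snps": [vars(s).copy() for s in config.snps],
        "phenotypes": [vars(p).copy() for p in config.phenotypes],
        "joint_effects": [vars(e).copy() for e in config.joint_effects],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    try:
        return SimulationConfig(
            n_lean=d.get("n_lean", N_LEAN),
            n_obese=d.get("n_obese", N_OBESE),
            snps=[SnpSpec(**s) for s in d.get("snps", [])],
            phenotypes=[PhenotypeSpec(**p) for p in d.get("phenotypes", [])],
            joint_effects=[JointEffectSpec(**e) for e in d.get("joint_effects", [])],
            seed=d.get("seed", 0),
        )
    except TypeError as exc:
        raise ValidationError(f"invalid simulation config: {exc}") from exc


def load_simulation_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return config_from_dict(data)


def save_simulation_config(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
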
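"""Genotype/phenotype table IO, anthropometric indices, and genotype counting.

Genotype CSV schema: header ``sample_id,<rsID>,...``; each call is a
two-character allele string (e.g. ``CT``); an empty cell is a missing call.
Heterozygotes are normalised to a canonical major-then-minor allele order on
read, so ``TC`` and ``CT`` denote the same genotype.

Phenotype CSV schema: one row per sample with columns ``sample_id, age,
height, body_mass, waist, hip, FBM_pct, LBM_pct, BMR, SBP, DBP`` plus the
derived ``BMI``, ``WHR`` and the ``group`` label (``lean``/``obese``/
``excluded``).  All files are UTF-8, comma-separated, ``.`` decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .reference import STUDY_SNP_PANEL

RAW_PHENOTYPES = (
    "age",
    "height",
    "body_mass",
    "waist",
    "hip",
    "FBM_pct",
    "LBM_pct",
    "BMR",
    "SBP",
    "DBP",
)
DERIVED_PHENOTYPES = ("BMI", "WHR")

BMI_LEAN_MAX = 25.0   # lean iff BMI strictly below
BMI_OBESE_MIN = 30.0  # obese iff BMI strictly above; in between -> excluded
WHR_VISCERAL_CUTOFF = 0.85  # visceral iff WHR strictly above (women)
SBP_HYPERTENSION = 140.0
DBP_HYPERTENSION = 90.0


@dataclass
class GenotypeMatrix:
    """Samples x SNPs grid of biallelic genotype calls.

    ``data`` is indexed by sample id with one column per SNP; cells hold the
    canonical two-character genotype string or NaN for missing.  ``alleles``
    maps each SNP id to its (major, minor) allele pair.
    """

    data: pd.DataFrame
    alleles: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        missing = [s for s in self.data.columns if s not in self.alleles]
        if missing:
            raise ValidationError(f"no allele declaration for SNP(s): {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.data.columns)

    def genotype_labels(self, snp_id: str) -> tuple[str, str, str]:
        """Canonical (major-hom, het, minor-hom) genotype strings for a SNP."""
        major, minor = self.alleles[snp_id]
        return major + major, major + minor, minor + minor

    def calls(self, snp_id: str) -> pd.Series:
        if snp_id not in self.data.columns:
            raise ValidationError(f"unknown SNP: {snp_id!r}")
        return self.data[snp_id]


@dataclass
class GenotypeCountTable:
    """Genotype and derived allele counts for one SNP in one group."""

    snp_id: str
    group: str
    n_major_hom: int
    n_het: int
    n_minor_hom: int
    n_missing: int = 0
    major_allele: str = ""
    minor_allele: str = ""

    def __post_init__(self) -> None:
        for name in ("n_major_hom", "n_het", "n_minor_hom", "n_missing"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def genotype_counts(self) -> tuple[int, int, int]:
        return (self.n_major_hom, self.n_het, self.n_minor_hom)

    @property
    def n(self) -> int:
        """Non-missing sample count."""
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(major, minor) allele counts; sum to 2 * n."""
        return (2 * self.n_major_hom + self.n_het, 2 * self.n_minor_hom + self.n_het)

    def genotype_percentages(self) -> tuple[float, float, float]:
        if self.n == 0:
            raise ValidationError(f"{self.snp_id}/{self.group}: no non-missing calls")
        return tuple(100.0 * c / self.n for c in self.genotype_counts)


def _canonicalise_call(call: str, major: str, minor: str, where: str) -> str:
    if len(call) != 2 or any(ch not in (major, minor) for ch in call):
        raise ParseError(
            f"{where}: call {call!r} uses alleles outside declared {major}/{minor}"
        )
    if set(call) == {major, minor}:
        return major + minor
    return call


def _infer_alleles(column: pd.Series, snp_id: str) -> tuple[str, str]:
    """Infer (major, minor) from observed calls: major = most frequent allele."""
    counts: dict[str, int] = {}
    for call in column.dropna():
        for ch in str(call):
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        raise ParseError(f"column {snp_id}: no calls to infer alleles from")
    if len(counts) > 2:
        raise ParseError(
            f"column {snp_id}: more than two alleles observed: {sorted(counts)}"
        )
    ordered = sorted(counts, key=lambda a: (-counts[a], a))
    if len(ordered) == 1:
        # monomorphic: pick an arbitrary distinct minor so labels stay well formed
        other = "A" if ordered[0] != "A" else "C"
        ordered.append(other)
    return ordered[0], ordered[1]


def read_genotype_csv(path, alleles: dict[str, tuple[str, str]] | None = None) -> GenotypeMatrix:
    """Read a genotype CSV into a :class:`GenotypeMatrix`.

    Allele declarations are taken from ``alleles`` when given; SNPs from the
    study panel fall back to the panel's declaration, and any remaining
    column has its major/minor alleles inferred from the observed calls.
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample_id(s): {dupes}")
    resolved: dict[str, tuple[str, str]] = {}
    for snp_id in df.columns:
        if alleles and snp_id in alleles:
            resolved[snp_id] = alleles[snp_id]
        elif snp_id in STUDY_SNP_PANEL:
            _, major, minor, _ = STUDY_SNP_PANEL[snp_id]
            resolved[snp_id] = (major, minor)
        else:
            resolved[snp_id] = _infer_alleles(df[snp_id], snp_id)
    for snp_id in df.columns:
        major, minor = resolved[snp_id]
        df[snp_id] = [
            np.nan
            if pd.isna(call)
            else _canonicalise_call(str(call), major, minor, f"row {sid}, column {snp_id}")
            for sid, call in df[snp_id].items()
        ]
    return GenotypeMatrix(data=df, alleles=resolved)


def write_genotype_csv(gm: GenotypeMatrix, path) -> None:
    gm.data.to_csv(path, index_label="sample_id", na_rep="")


def read_genotype_vcf(path, alleles: dict[str, tuple[str, str]] | None = None) -> GenotypeMatrix:
    """Import biallelic SNP genotypes from the GT field of a VCF.

    Convenience reader for unphased diploid records; multi-allelic records
    are rejected.  The REF allele is taken as major unless overridden via
    ``alleles``.  VCF writing is not supported.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        columns: dict[str, list] = {}
        resolved: dict[str, tuple[str, str]] = {}
        for rec in vcf:
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(f"{snp_id}: only biallelic records are supported")
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise ParseError(f"{snp_id}: only SNPs are supported")
            major, minor = rec.ref, rec.alts[0]
            if alleles and snp_id in alleles:
                major, minor = alleles[snp_id]
                if {major, minor} != {rec.ref, rec.alts[0]}:
                    raise ParseError(f"{snp_id}: declared alleles disagree with VCF")
            site = {0: major, 1: minor}
            calls = []
            for sample in samples:
                gt = rec.samples[sample]["GT"]
                if gt is None or any(a is None for a in gt):
                    calls.append(np.nan)
                    continue
                if len(gt) != 2:
                    raise ParseError(f"{snp_id}/{sample}: diploid GT required")
                pair = "".join(site[a] for a in sorted(gt))
                calls.append(_canonicalise_call(pair, major, minor, f"{snp_id}/{sample}"))
            columns[snp_id] = calls
            resolved[snp_id] = (major, minor)
    data = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    return GenotypeMatrix(data=data, alleles=resolved)


def read_phenotype_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in RAW_PHENOTYPES if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing phenotype column(s): {missing}")
    return df


def write_phenotype_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index_label="sample_id")


def derive_indices(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with BMI (kg/m^2) and WHR columns derived.

    BMI = body_mass / (height/100)^2; WHR = waist / hip.  Full floating
    precision is retained; rounding happens only in rendered tables.
    """
    for col in ("height", "body_mass", "waist", "hip"):
        if col not in phenotypes.columns:
            raise ValidationError(f"derive_indices: missing column {col!r}")
        if (pd.to_numeric(phenotypes[col]) <= 0).any():
            bad = phenotypes.index[pd.to_numeric(phenotypes[col]) <= 0].tolist()
            raise ValidationError(f"non-positive {col} for sample(s): {bad[:5]}")
    out = phenotypes.copy()
    out["BMI"] = out["body_mass"] / (out["height"] / 100.0) ** 2
    out["WHR"] = out["waist"] / out["hip"]
    return out


def classify_bmi_group(bmi):
    """Classify BMI into 'lean' (< 25), 'obese' (> 30) or 'excluded'.

    The boundary values 25 and 30 are excluded (strict inequalities), matching
    the enrolment design that admits only BMI < 25 or BMI > 30.
    Accepts a scalar or an array/Series.
    """
    arr = np.asarray(bmi, dtype=float)
    out = np.where(arr < BMI_LEAN_MAX, "lean", np.where(arr > BMI_OBESE_MIN, "obese", "excluded"))
    if np.ndim(bmi) == 0:
        return out.item()
    if isinstance(bmi, pd.Series):
        return pd.Series(out, index=bmi.index, name="group")
    return out


def classify_fat_distribution(whr):
    """'visceral' iff WHR > 0.85 (strict), else 'non_visceral'."""
    arr = np.asarray(whr, dtype=float)
    out = np.where(arr > WHR_VISCERAL_CUTOFF, "visceral", "non_visceral")
    return out.item() if np.ndim(whr) == 0 else out


def classify_hypertension(sbp, dbp):
    """True iff SBP >= 140 mmHg and/or DBP >= 90 mmHg."""
    out = (np.asarray(sbp, dtype=float) >= SBP_HYPERTENSION) | (
        np.asarray(dbp, dtype=float) >= DBP_HYPERTENSION
    )
    return bool(out) if np.ndim(out) == 0 else out


def count_genotypes(
    gm: GenotypeMatrix, groups: pd.Series, snp_id: str
) -> tuple[GenotypeCountTable, GenotypeCountTable]:
    """Per-group genotype counts for one SNP -> (lean table, obese table).

    Missing calls are dropped from that SNP's counts only (complete-case per
    SNP) and reported in ``n_missing``.  Samples with group labels other than
    lean/obese are ignored.
    """
    calls = gm.calls(snp_id)
    labels = gm.genotype_labels(snp_id)
    major, minor = gm.alleles[snp_id]
    tables = []
    for group in ("lean", "obese"):
        members = groups.index[groups == group]
        sub = calls.reindex(members)
        n_missing = int(sub.isna().sum())
        counts = sub.value_counts()
        tables.append(
            GenotypeCountTable(
                snp_id=snp_id,
                group=group,
                n_major_hom=int(counts.get(labels[0], 0)),
                n_het=int(counts.get(labels[1], 0)),
                n_minor_hom=int(counts.get(labels[2], 0)),
                n_missing=n_missing,
                major_allele=major,
                minor_allele=minor,
            )
        )
    return tables[0], tables[1]
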
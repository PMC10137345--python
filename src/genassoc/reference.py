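"""Reference data for the postmenopausal obesity candidate-gene study.

Holds the study's SNP panel (PPAR-gamma2 rs1801282 Pro12Ala and rs3856806
C1431T, beta3-adrenergic receptor rs4994 Trp64Arg, and FAM13A rs1903003,
rs7671167, rs2869967), the published per-group genotype counts for the
105 lean / 124 obese cohort, and the per-group phenotype summary statistics
(mean, SD) used as simulator defaults.

Only per-SNP marginal counts were published; the subject-level joint
genotype structure is not public.  ``study_genotype_matrix`` therefore
reconstructs a sample-level matrix whose per-SNP, per-group marginals match
the published counts exactly, while the joint distribution across SNPs is
an arbitrary (deterministic) pairing — sufficient for single-SNP
association and HWE analyses, not for co-existence analyses.
"""

from __future__ import annotations

import pandas as pd

N_LEAN = 105
N_OBESE = 124

#: snp_id -> (gene, major_allele, minor_allele, protein/codon label or None)
#: The codon naming for rs4994 is stored as free text only; the site is
#: treated as a generic biallelic SNP throughout.
STUDY_SNP_PANEL: dict[str, tuple[str, str, str, str | None]] = {
    "rs1801282": ("PPARG2", "C", "G", "Pro12Ala"),
    "rs3856806": ("PPARG2", "C", "T", "C1431T"),
    "rs4994": ("ADRB3", "T", "C", "Trp64Arg"),
    "rs7671167": ("FAM13A", "T", "C", None),
    "rs1903003": ("FAM13A", "T", "C", None),
    "rs2869967": ("FAM13A", "T", "C", None),
}

#: Published genotype counts per SNP and group as
#: (n_major_hom, n_het, n_minor_hom).  Counts sum to the group sizes.
STUDY_GENOTYPE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "rs1801282": {"lean": (74, 30, 1), "obese": (93, 27, 4)},
    "rs3856806": {"lean": (71, 33, 1), "obese": (84, 35, 5)},
    "rs4994": {"lean": (84, 20, 1), "obese": (102, 21, 1)},
    "rs7671167": {"lean": (33, 52, 20), "obese": (32, 66, 26)},
    "rs1903003": {"lean": (17, 51, 37), "obese": (37, 65, 22)},
    "rs2869967": {"lean": (27, 52, 26), "obese": (34, 65, 25)},
}

#: Published phenotype summaries: name -> (mean_lean, sd_lean, mean_obese, sd_obese).
#: Units: age years, height cm, body_mass kg, waist/hip cm, FBM/LBM percent of
#: body mass, BMR kcal/day, SBP/DBP mmHg.
STUDY_PHENOTYPES: dict[str, tuple[float, float, float, float]] = {
    "age": (58.91, 5.65, 59.57, 5.01),
    "height": (161.80, 5.84, 160.26, 6.01),
    "body_mass": (62.10, 6.91, 87.27, 11.91),
    "waist": (77.67, 7.85, 100.15, 9.21),
    "hip": (97.62, 5.40, 115.19, 8.45),
    "FBM_pct": (37.62, 4.02, 47.73, 4.14),
    "LBM_pct": (62.44, 3.89, 52.23, 4.14),
    "BMR": (1277.34, 103.10, 1431.23, 114.33),
    "SBP": (137.06, 21.35, 145.27, 23.68),
    "DBP": (84.38, 12.71, 91.27, 13.57),
}


def study_minor_allele_frequency(snp_id: str, group: str) -> float:
    """Minor allele frequency implied by the published genotype counts."""
    hom_major, het, hom_minor = STUDY_GENOTYPE_COUNTS[snp_id][group]
    n = hom_major + het + hom_minor
    return (2 * hom_minor + het) / (2 * n)


def study_genotype_matrix():
    """Sample-level genotype matrix reproducing the published marginal counts.

    Returns
    -------
    (GenotypeMatrix, pandas.Series)
        The matrix (229 samples x 6 SNPs) and the group label per sample
        (``lean``/``obese``).  Per-SNP per-group genotype counts equal the
        published table; the joint structure across SNPs is synthetic.
    """
    from .cohort import GenotypeMatrix

    sample_ids = [f"L{i:03d}" for i in range(1, N_LEAN + 1)] + [
        f"O{i:03d}" for i in range(1, N_OBESE + 1)
    ]
    groups = pd.Series(
        ["lean"] * N_LEAN + ["obese"] * N_OBESE, index=sample_ids, name="group"
    )
    columns = {}
    for snp_id, (gene, major, minor, _) in STUDY_SNP_PANEL.items():
        labels = (major + major, major + minor, minor + minor)
        calls = []
        for group in ("lean", "obese"):
            for label, count in zip(labels, STUDY_GENOTYPE_COUNTS[snp_id][group]):
                calls.extend([label] * count)
        columns[snp_id] = calls
    data = pd.DataFrame(columns, index=sample_ids)
    alleles = {snp: (major, minor) for snp, (_, major, minor, _) in STUDY_SNP_PANEL.items()}
    return GenotypeMatrix(data=data, alleles=alleles), groups
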
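"""Published summary statistics used as worked examples.

These are the printed group-level numbers from the BFMI × B6N
reciprocal-cross liver RNA-seq study this package's methods follow:
phenotype group means of 10-week-old F1 males, the per-gene mean
log-RPKM values and fold changes of the highly differentially expressed
genes, and the per-SNP BFMI-allele percentages of the allelic-imbalance
loci.  They serve as fixed inputs for worked examples and consistency
checks of the arithmetic conventions (fold change as a ratio of group
means on the ln(RPKM+1) scale; allelic-imbalance differences in
percentage points); they are not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "phenotype_group_means",
    "de_gene_table",
    "allelic_imbalance_table",
]

# trait -> fostering -> (patBFMI mean, patBFMI sd, matBFMI mean, matBFMI sd);
# males only, values already litter-size adjusted except glucose and liver TG
_PHENO = {
    "body_mass": {"maternal": (34.23, 3.26, 36.82, 3.96),
                  "cross_fostered": (34.27, 3.41, 35.63, 2.65)},
    "fat_mass": {"maternal": (3.86, 1.49, 7.06, 2.56),
                 "cross_fostered": (4.06, 2.06, 5.54, 1.74)},
    "lean_mass": {"maternal": (27.54, 2.06, 26.93, 2.10),
                  "cross_fostered": (29.54, 1.84, 29.61, 1.68)},
    "fat_lean_ratio": {"maternal": (0.14, 0.05, 0.26, 0.08),
                       "cross_fostered": (0.14, 0.06, 0.19, 0.06)},
    "liver_mass": {"maternal": (1.55, 0.23, 1.68, 0.18),
                   "cross_fostered": (1.66, 0.21, 1.75, 0.15)},
    "liver_tg_protein": {"maternal": (0.45, 0.09, 0.59, 0.22),
                         "cross_fostered": (0.15, 0.09, 0.21, 0.08)},
    "blood_glucose": {"maternal": (165.33, 27.20, 174.25, 23.80),
                      "cross_fostered": (137.82, 19.07, 151.83, 22.70)},
}


def phenotype_group_means() -> pd.DataFrame:
    """Male F1 phenotype summaries per fostering condition."""
    rows = [
        {"trait": t, "fostering": f, "mean_pat": v[0], "sd_pat": v[1],
         "mean_mat": v[2], "sd_mat": v[3]}
        for t, d in _PHENO.items()
        for f, v in d.items()
    ]
    return pd.DataFrame(rows)


# gene, chrom, mean ln(RPKM+1) patBFMI, matBFMI, printed fold change, t-test p
_DE_ROWS = [
    ("Slc16a7", "10", 1.91, 2.30, 1.20, 0.0007),
    ("Nlrp12", "7", 2.66, 2.19, 0.82, 0.0009),
    ("Il1r1", "1", 2.16, 1.60, 0.74, 0.0019),
    ("St5", "7", 1.97, 1.61, 0.82, 0.0029),
    ("Hmgcr", "13", 3.01, 3.98, 1.32, 0.0034),
    ("Scara5", "14", 1.23, 0.55, 0.44, 0.0050),
    ("Gpr110", "17", 1.48, 0.85, 0.57, 0.0092),
    ("Grem2", "1", 1.50, 1.11, 0.74, 0.0102),
    ("Fasn", "11", 4.47, 5.41, 1.21, 0.0110),
    ("Selenbp2", "3", 5.72, 4.76, 0.83, 0.0113),
    ("Cyp4a14", "4", 3.58, 4.74, 1.32, 0.0119),
    ("Cyp2c38", "19", 1.46, 2.33, 1.60, 0.0122),
    ("Crat", "2", 1.79, 2.27, 1.26, 0.0128),
    ("Coq10b", "1", 1.42, 1.98, 1.39, 0.0138),
    ("Rai14", "15", 1.98, 1.64, 0.83, 0.0144),
    ("Mup-ps20", "4", 1.46, 0.51, 0.35, 0.0145),
    ("Arntl", "7", 1.90, 1.05, 0.55, 0.0151),
    ("Acnat2", "4", 2.37, 3.22, 1.36, 0.0155),
    ("Abcd2", "15", 1.14, 1.72, 1.51, 0.0157),
    ("Cyp2c39", "19", 2.77, 3.57, 1.29, 0.0157),
    ("Slc45a3", "1", 2.15, 1.72, 0.80, 0.0166),
    ("Sntg2", "12", 1.75, 1.45, 0.83, 0.0187),
    ("Per2", "1", 1.26, 1.67, 1.32, 0.0208),
    ("Hcn3", "3", 0.95, 1.51, 1.60, 0.0208),
    ("Gas6", "8", 2.26, 2.73, 1.21, 0.0209),
    ("Serpina12", "12", 2.40, 1.94, 0.81, 0.0211),
    ("Elovl6", "3", 3.20, 4.17, 1.30, 0.0214),
    ("Acsl3", "1", 2.24, 2.71, 1.21, 0.0215),
    ("Acot4", "12", 0.93, 1.66, 1.79, 0.0219),
    ("Slc20a1", "2", 1.54, 1.87, 1.21, 0.0219),
    ("B3galt1", "2", 1.52, 1.07, 0.70, 0.0230),
    ("Cyp7b1", "3", 5.11, 4.23, 0.83, 0.0257),
    ("Cyp4a10", "4", 3.78, 5.02, 1.33, 0.0260),
]


def de_gene_table() -> pd.DataFrame:
    """Highly differentially expressed genes between the reciprocal F1
    males: group means on the log layer and the published fold change."""
    return pd.DataFrame(
        _DE_ROWS,
        columns=["gene", "chrom", "mean_log_pat", "mean_log_mat",
                 "fold_change_printed", "p_value"],
    )


# chrom, pos, ref, alt(BFMI allele), gene, % BFMI allele patBFMI, matBFMI,
# printed ratio difference (percentage points; None where coverage failed)
_ASE_ROWS = [
    ("2", 91712576, "C", "T", "Harbi1", 48.1, 79.7, 31.5),
    ("2", 152687856, "C", "T", "Mcts2", 88.9, 7.2, 81.8),
    ("2", 152704657, "A", "T", "H13", 18.4, 75.9, 57.5),
    ("2", 152705549, "G", "A", "H13", 7.9, 100.0, 92.1),
    ("7", 6704437, "C", "T", "Peg3", 93.6, None, None),
    ("7", 6706584, "A", "G", "Peg3", 100.0, None, None),
    ("11", 22956525, "G", "A", "Commd1", 37.3, 57.7, 20.3),
    ("11", 22972794, "G", "T", "Commd1", 98.8, 0.0, 98.8),
    ("11", 22974882, "G", "A", "Zrsr1", 95.2, 4.6, 90.7),
    ("11", 109933190, "T", "C", "Abca8b", 57.6, 30.9, 26.7),
    ("11", 109933214, "C", "T", "Abca8b", 60.8, 38.5, 22.4),
    ("11", 109974591, "A", "C", "Abca8b", 67.7, 45.7, 22.0),
    ("12", 104081368, "A", "G", "Serpina4-ps1", 24.6, 60.9, 36.3),
    ("12", 104081522, "G", "A", "Serpina4-ps1", 27.2, 58.0, 30.8),
    ("17", 12380069, "G", "T", "Plg", 22.6, 71.7, 49.1),
    ("17", 78969687, "T", "C", "Prkd3", 77.5, 57.3, 20.2),
]


def allelic_imbalance_table() -> pd.DataFrame:
    """SNPs with allelic imbalance in both cross directions; the
    alternative allele is anchored to the BFMI allele."""
    return pd.DataFrame(
        _ASE_ROWS,
        columns=["chrom", "pos", "ref", "alt", "gene", "pct_alt_pat",
                 "pct_alt_mat", "ratio_diff_printed"],
    )
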
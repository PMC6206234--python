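"""Published aggregate tables of the three-center neuroblastoma study.

The source study genotyped five LMO1 SNPs in 313 eastern-Chinese
neuroblastoma cases and 762 cancer-free controls and published its full
genotype-by-status counts, combined protective-genotype grouping and
EM-derived haplotype counts.  Those printed aggregates are reproduced
here as plain data so every crude statistic of the study can be
recomputed from them; no individual-level data were deposited.
"""

from __future__ import annotations

from .cohort import GenotypeCounts, STUDY_PANEL

N_CASES = 313
N_CONTROLS = 762

#: Genotype counts by variant-allele dose (0/1/2), study order.
GENOTYPE_COUNTS = {
    "rs110419": GenotypeCounts("rs110419", (150, 118, 45), (279, 355, 128)),
    "rs4758051": GenotypeCounts("rs4758051", (138, 123, 52), (256, 364, 142)),
    "rs10840002": GenotypeCounts("rs10840002", (120, 128, 65), (240, 375, 147)),
    "rs204938": GenotypeCounts("rs204938", (200, 97, 16), (476, 258, 28)),
    "rs2168101": GenotypeCounts("rs2168101", (214, 85, 14), (401, 310, 51)),
}

#: Combined protective-genotype grouping (0-3 vs 4-5 protective genotypes):
#: (cases 0-3, cases 4-5, controls 0-3, controls 4-5).
COMBINED_COUNTS = (213, 100, 401, 361)

#: Published control-group demographics used by the synthetic generator.
AGE_MEAN_CONTROLS = 33.04
AGE_SD_CONTROLS = 30.30
AGE_MIN = 0.001
AGE_MAX = 132.0
P_MALE_CONTROLS = 422 / 762
#: Tumor site-of-origin proportions among cases
#: (adrenal, retroperitoneal, mediastinum, other).
SITE_PROPORTIONS = (0.2173, 0.4026, 0.3163, 0.0639)

#: Haplotype counts over the 5-SNP panel (locus order = panel order,
#: alleles per locus as in each SnpDef).  Chromosome totals: 626 case,
#: 1524 control.
HAPLOTYPE_CASE_COUNTS = {
    "AGAAG": 271, "AGAAT": 0, "AGAGG": 33, "AGGAG": 16, "AGGGG": 7,
    "AGGGT": 0, "AAAAG": 1, "AAGAG": 54, "AAGAT": 0, "AAGGG": 36,
    "GGAAG": 39, "GGAAT": 9, "GGAGG": 12, "GGAGT": 0, "GGGAG": 6,
    "GGGAT": 3, "GGGGG": 2, "GGGGT": 1, "GAAAG": 2, "GAAAT": 1,
    "GAGAG": 21, "GAGAT": 74, "GAGGG": 13, "GAGGT": 25,
}
HAPLOTYPE_CONTROL_COUNTS = {
    "AGAAG": 606, "AGAAT": 2, "AGAGG": 67, "AGGAG": 10, "AGGGG": 8,
    "AGGGT": 1, "AAAAG": 5, "AAGAG": 156, "AAGAT": 1, "AAGGG": 57,
    "GGAAG": 106, "GGAAT": 24, "GGAGG": 37, "GGAGT": 6, "GGGAG": 1,
    "GGGAT": 5, "GGGGG": 1, "GGGGT": 2, "GAAAG": 1, "GAAAT": 1,
    "GAGAG": 29, "GAGAT": 263, "GAGGG": 28, "GAGGT": 107,
}
REFERENCE_HAPLOTYPE = "AGAAG"

#: Control haplotype frequencies (counts / 1524) — the default haplotype
#: pool of the synthetic cohort generator.
CONTROL_HAPLOTYPE_FREQS = {
    h: c / 1524 for h, c in HAPLOTYPE_CONTROL_COUNTS.items() if c > 0
}

#: Published significant single-SNP/combined findings with their crude
#: ORs, 95% CIs, p-values and the study's printed statistical power —
#: the inputs of the false-positive report probability analysis.
#: p-values are the full-precision crude Wald p-values where the study
#: printed them (its FPRP table rounds the display column).
SIGNIFICANT_FINDINGS = [
    # (label, OR, ci_low, ci_high, p, printed_power)
    ("rs110419 AG vs AA", 0.62, 0.46, 0.82, 0.0011, 0.361),
    ("rs110419 GG vs AA", 0.65, 0.44, 0.97, 0.034, 0.458),
    ("rs110419 AG/GG vs AA", 0.63, 0.48, 0.82, 0.0006, 0.317),
    ("rs4758051 AG vs GG", 0.63, 0.47, 0.84, 0.0017, 0.415),
    ("rs4758051 AA vs GG", 0.68, 0.47, 0.99, 0.046, 0.547),
    ("rs4758051 AG/AA vs GG", 0.64, 0.49, 0.84, 0.0012, 0.377),
    ("rs10840002 AG vs AA", 0.68, 0.51, 0.92, 0.012, 0.666),
    ("rs10840002 AG/GG vs AA", 0.74, 0.56, 0.97, 0.031, 0.764),
    ("rs2168101 GT vs GG", 0.51, 0.38, 0.69, 7.7e-6, 0.045),
    ("rs2168101 TT vs GG", 0.51, 0.28, 0.95, 0.034, 0.192),
    ("rs2168101 GT/TT vs GG", 0.51, 0.39, 0.68, 2.6e-6, 0.035),
    ("protective 4-5 vs 0-3", 0.52, 0.40, 0.69, 4.1e-6, 0.042),
]

PANEL = STUDY_PANEL
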
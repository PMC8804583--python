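"""Published summary statistics of the high-myopia replication panels.

These are the printed inputs of the replication analyses: minor-allele
frequencies of the candidate SNPs in the combined mainland validation panel
(1,091 cases vs 52,708 population-database controls), the single-SNP Taiwan
(KMUH) replication panel (991 cases vs 1,025 controls), and the
stage-level odds ratios entering the fixed-effect meta-analysis of the
PDE4B intronic variant rs10889602.  Everything downstream (odds ratios,
chi-square and trend p-values, the meta OR, the Bonferroni threshold) is
recomputed from these numbers at run time.
"""

from __future__ import annotations

VALIDATION_N_CASE = 1091
VALIDATION_N_CONTROL = 52708

# snp_id -> (chrom, pos_b37, risk_allele, maf_case, maf_control, published_or)
# The published OR column is carried for cross-checks only; `reproduces`
# marks rows whose printed MAFs reproduce the printed OR to +/-0.01 (one row,
# rs600242, does not — its frequencies are rounded too coarsely).
VALIDATION_SUMMARY: dict[str, dict] = {
    "rs11580093": dict(chrom=1, pos=53_532_606, gene="PODN", risk_allele="C",
                       maf_case=0.0339, maf_control=0.0321, published_or=1.06,
                       reproduces=True),
    "rs10889602": dict(chrom=1, pos=66_573_381, gene="PDE4B", risk_allele="G",
                       maf_case=0.0692, maf_control=0.0546, published_or=1.28,
                       reproduces=True),
    "rs7762018": dict(chrom=6, pos=16_877_190, gene="PHF10", risk_allele="A",
                      maf_case=0.322, maf_control=0.299, published_or=1.11,
                      reproduces=True),
    "rs600242": dict(chrom=11, pos=86_402_877, gene="ME3", risk_allele="G",
                     maf_case=0.184, maf_control=0.176, published_or=1.04,
                     reproduces=False),
    "rs4149152": dict(chrom=12, pos=21_047_074, gene="SLCO1B3", risk_allele="G",
                      maf_case=0.0875, maf_control=0.0814, published_or=1.08,
                      reproduces=True),
    "rs2193015": dict(chrom=12, pos=97_563_086, gene="NEDD1", risk_allele="C",
                      maf_case=0.404, maf_control=0.432, published_or=1.12,
                      reproduces=True),
    "rs9676191": dict(chrom=18, pos=49_625_503, gene="DCC", risk_allele="C",
                      maf_case=0.160, maf_control=0.132, published_or=1.25,
                      reproduces=True),
}

KMUH_N_CASE = 991
KMUH_N_CONTROL = 1025
KMUH_RS10889602 = dict(maf_case=0.0400, maf_control=0.0524,
                       published_or=1.32, published_ci=(0.98, 1.78))

# stage-level rs10889602 summaries entering the meta-analysis:
# (or, ci_low, ci_high)
META_RS10889602_STUDIES = [
    (1.28, 1.08, 1.52),  # mainland validation panel
    (1.32, 0.98, 1.78),  # KMUH replication panel
]
META_RS10889602_PUBLISHED_OR = 1.29

N_CANDIDATE_SNPS = 9  # SNPs carried into replication; Bonferroni denominator
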
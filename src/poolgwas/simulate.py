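"""Synthetic data generator for the pooled-GWAS pipeline.

Emulates a two-batch DNA-pooling case-control design: case pools of 331 and
176 subjects against control pools of 145 and 149, three replicate arrays per
pool, two-channel (Cy3/Cy5) intensities per SNP probe, per-replicate
measurement noise, multiplicative channel-gain imbalance (the source of the
well-known allele-frequency overestimation of pooling), occasional bad
arrays, and optional population stratification.  Individual genotypes for
replication-style analyses are drawn under Hardy-Weinberg equilibrium.

All randomness flows through :class:`numpy.random.Generator` instances seeded
explicitly; identical seeds yield byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PoolSpec",
    "PoolDesign",
    "TruthPanel",
    "GenotypeMatrix",
    "default_design",
    "risk_allele_frequency",
    "simulate_truth",
    "simulate_pool_intensities",
    "simulate_genotypes",
    "simulate_two_locus",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PoolSpec:
    """One DNA pool: equimolar mix of ``n_subjects`` individuals."""

    pool_id: str
    group: str  # "case" or "control"
    batch: int
    n_subjects: int

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")


@dataclass
class PoolDesign:
    """Pooling design plus the array error model.

    Parameters
    ----------
    pools
        The case/control pools, each tagged with an experimental batch.
    replicates_per_pool
        Number of replicate arrays hybridised per pool (>= 1).
    sd_array
        Per-replicate measurement SD on the allele-frequency scale.
    gain_ratio
        Multiplicative Cy3/Cy5 channel imbalance g; raw intensities are
        x = I*g*f and y = I*(1-f), so E[x/(x+y)] = g*f/(g*f + 1 - f) > f
        whenever g > 1 — the documented overestimation of pooled frequencies.
    intensity_scale, intensity_sigma
        Total probe intensity I is lognormal with median ``intensity_scale``
        and log-SD ``intensity_sigma``.
    bad_array_rate
        Probability that a replicate array is "bad": its per-SNP frequencies
        are randomly permuted across SNPs, which destroys the inter-replicate
        correlation that the R >= 0.99 QC filter tests.
    stratification_delta, stratification_fraction
        Ancestry confounding: a random ``stratification_fraction`` of SNPs
        receive a ``stratification_delta`` frequency shift in the case group
        (same SNP set in every case pool).
    """

    pools: list[PoolSpec]
    replicates_per_pool: int = 3
    sd_array: float = 0.01
    gain_ratio: float = 1.05
    intensity_scale: float = 2000.0
    intensity_sigma: float = 0.25
    bad_array_rate: float = 1.0 / 6.0
    stratification_delta: float = 0.0
    stratification_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.pools:
            raise ValueError("design needs at least one pool")
        if self.replicates_per_pool < 1:
            raise ValueError("replicates_per_pool must be >= 1")
        if self.gain_ratio < 0:
            raise ValueError("gain_ratio must be >= 0")
        for p in (self.bad_array_rate, self.stratification_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def default_design(**overrides) -> PoolDesign:
    """The two-batch study design: case pools of 331 and 176 subjects vs
    control pools of 145 and 149, three replicates each."""
    design = PoolDesign(
        pools=[
            PoolSpec("case_b1", "case", 1, 331),
            PoolSpec("ctrl_b1", "control", 1, 145),
            PoolSpec("case_b2", "case", 2, 176),
            PoolSpec("ctrl_b2", "control", 2, 149),
        ]
    )
    return replace(design, **overrides) if overrides else design


@dataclass
class TruthPanel:
    """Ground-truth variant panel.

    ``variants`` columns: snp_id, chrom, pos, allele_a, allele_b, f_control,
    or_risk, f_case.  allele_b is the risk/coded allele whose frequency the
    f_* columns give; f_case follows from f_control and the allelic odds
    ratio via f_case = OR*f / (1 - f + OR*f).
    """

    variants: pd.DataFrame

    def __post_init__(self) -> None:
        f, fc = self.variants["f_control"], self.variants["f_case"]
        if ((f < 0) | (f > 1) | (fc < 0) | (fc > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        if (self.variants["or_risk"] < 0).any():
            raise ValueError("odds ratios must be >= 0")

    @property
    def n_snps(self) -> int:
        return len(self.variants)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype table.

    ``samples`` columns: sample_id, status (1=case/0=control), sex, age, then
    one column per snp_id with 0/1/2 counts of the coded (allele_b) allele,
    NaN for missing.  ``variants``: chrom, snp_id, pos, allele_a, allele_b.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame

    @property
    def snp_ids(self) -> list[str]:
        return list(self.variants["snp_id"])

    def genotype_values(self, snp_id: str) -> np.ndarray:
        if snp_id not in self.samples.columns:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return self.samples[snp_id].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# operations


def risk_allele_frequency(f_control, or_risk):
    """Case-group frequency implied by a control frequency and allelic OR:
    f_case = OR*f / (1 - f + OR*f)."""
    f = np.asarray(f_control, dtype=float)
    orr = np.asarray(or_risk, dtype=float)
    return orr * f / (1.0 - f + orr * f)


def simulate_truth(
    n_snps: int,
    maf_sampler=None,
    causal_spec: list[tuple[int, float]] | None = None,
    seed: int = 0,
) -> TruthPanel:
    """Draw a ground-truth panel of ``n_snps`` biallelic SNPs.

    ``maf_sampler(rng, n)`` returns control-group frequencies of the coded
    allele.  The default is Uniform(0.05, 0.95): on a real array the coded
    allele is arbitrary with respect to frequency, so coded frequencies are
    symmetric about 0.5 (MAF >= 0.05 here).  ``causal_spec`` lists
    (index, odds_ratio) pairs for risk loci — every other SNP gets OR = 1.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        f_control = rng.uniform(0.05, 0.95, size=n_snps)
    else:
        f_control = np.asarray(maf_sampler(rng, n_snps), dtype=float)
    or_risk = np.ones(n_snps)
    for idx, orv in causal_spec or []:
        if not 0 <= idx < n_snps:
            raise IndexError(f"causal index {idx} out of range for {n_snps} SNPs")
        if orv <= 0:
            raise ValueError(f"odds ratio at index {idx} must be > 0")
        or_risk[idx] = orv
    width = len(str(n_snps))
    variants = pd.DataFrame(
        {
            "snp_id": [f"snp{str(i).zfill(width)}" for i in range(n_snps)],
            "chrom": rng.integers(1, 23, size=n_snps),
            "pos": np.sort(rng.integers(1, 2_000_000_000, size=n_snps)),
            "allele_a": "A",
            "allele_b": "B",
            "f_control": f_control,
            "or_risk": or_risk,
        }
    )
    variants["f_case"] = risk_allele_frequency(f_control, or_risk)
    return TruthPanel(variants)


def simulate_pool_intensities(
    truth: TruthPanel, design: PoolDesign, seed: int = 0
) -> pd.DataFrame:
    """Simulate two-channel array intensities for every (SNP, pool, replicate).

    For each pool a realised pool frequency is drawn as
    Binomial(2*n_subjects, f_group) / (2*n_subjects); each replicate observes
    that frequency plus Normal(0, sd_array) noise (clipped to [0, 1]); the
    two channels are x_raw = I*gain_ratio*f and y_raw = I*(1-f) with
    lognormal total intensity I.  Bad replicates (probability
    ``bad_array_rate``) have their per-SNP frequencies permuted.

    Returns the intensity panel as a DataFrame with columns
    snp_id, chrom, pos, pool_id, group, batch, replicate, x_raw, y_raw.
    """
    if truth.n_snps == 0 or not design.pools:
        raise ValueError("truth panel and design must be non-empty")
    rng = np.random.default_rng(seed)
    v = truth.variants
    n = truth.n_snps

    strat_shift = np.zeros(n)
    if design.stratification_delta != 0.0:
        k = int(round(design.stratification_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        strat_shift[idx] = design.stratification_delta

    frames = []
    for pool in design.pools:
        f_group = (v["f_case"] if pool.group == "case" else v["f_control"]).to_numpy()
        if pool.group == "case":
            f_group = np.clip(f_group + strat_shift, 0.0, 1.0)
        m = 2 * pool.n_subjects
        f_pool = rng.binomial(m, f_group) / m
        for rep in range(1, design.replicates_per_pool + 1):
            f_rep = np.clip(f_pool + rng.normal(0.0, design.sd_array, size=n), 0.0, 1.0)
            if rng.random() < design.bad_array_rate:
                f_rep = rng.permutation(f_rep)
            intensity = design.intensity_scale * np.exp(
                rng.normal(0.0, design.intensity_sigma, size=n)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": v["snp_id"],
                        "chrom": v["chrom"],
                        "pos": v["pos"],
                        "pool_id": pool.pool_id,
                        "group": pool.group,
                        "batch": pool.batch,
                        "replicate": rep,
                        "x_raw": intensity * design.gain_ratio * f_rep,
                        "y_raw": intensity * (1.0 - f_rep),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_genotypes(
    truth: TruthPanel,
    n_case: int,
    n_control: int,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Individual 0/1/2 genotypes under Hardy-Weinberg equilibrium at the
    group-specific allele frequency, with sex/age covariates independent of
    genotype and outcome."""
    if n_case < 1 or n_control < 1:
        raise ValueError("sample counts must be >= 1")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    v = truth.variants
    status = np.r_[np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)]
    n_total = n_case + n_control
    geno = np.empty((n_total, truth.n_snps), dtype=float)
    for j, (fc, fk) in enumerate(zip(v["f_case"], v["f_control"])):
        f = np.where(status == 1, fc, fk)
        geno[:, j] = rng.binomial(2, f)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = np.nan
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{str(i).zfill(len(str(n_total)))}" for i in range(n_total)],
            "status": status,
            "sex": rng.integers(0, 2, size=n_total),
            "age": np.round(rng.normal(30.0, 8.0, size=n_total), 1),
        }
    )
    samples = pd.concat(
        [meta, pd.DataFrame(geno, columns=list(v["snp_id"]))], axis=1
    )
    variants = v[["chrom", "snp_id", "pos", "allele_a", "allele_b"]].copy()
    return GenotypeMatrix(samples, variants)


def two_locus_haplotype_freqs(f1: float, f2: float, r2_target: float) -> np.ndarray:
    """Haplotype frequencies (p11, p10, p01, p00) for coded-allele frequencies
    f1, f2 and a target r^2 with positive D = sqrt(r2 * f1(1-f1) f2(1-f2))."""
    for f in (f1, f2):
        if not 0.0 < f < 1.0:
            raise ValueError("allele frequencies must be in (0, 1)")
    if not 0.0 <= r2_target <= 1.0:
        raise ValueError("r2_target must be in [0, 1]")
    var = f1 * (1 - f1) * f2 * (1 - f2)
    d = np.sqrt(r2_target * var)
    d_max = min(f1 * (1 - f2), (1 - f1) * f2)
    if d > d_max + 1e-12:
        r2_max = d_max**2 / var
        raise ValueError(
            f"r2_target={r2_target:g} unachievable for f1={f1:g}, f2={f2:g}; "
            f"feasible maximum is r2={r2_max:.6g}"
        )
    p11 = f1 * f2 + d
    p10 = f1 * (1 - f2) - d
    p01 = (1 - f1) * f2 - d
    p00 = (1 - f1) * (1 - f2) + d
    return np.clip([p11, p10, p01, p00], 0.0, 1.0)


def simulate_two_locus(
    f1: float, f2: float, r2_target: float, n: int, seed: int = 0
) -> GenotypeMatrix:
    """Unphased genotypes at two loci: each individual is the sum of two
    haplotypes drawn from the four-haplotype distribution with the requested
    linkage disequilibrium."""
    if n < 1:
        raise ValueError("n must be >= 1")
    hap_freqs = two_locus_haplotype_freqs(f1, f2, r2_target)
    rng = np.random.default_rng(seed)
    # haplotypes coded (allele at locus1, allele at locus2)
    haps = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    draws = rng.choice(4, size=(n, 2), p=hap_freqs / hap_freqs.sum())
    geno = haps[draws[:, 0]] + haps[draws[:, 1]]
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "status": 0,
            "sex": 0,
            "age": 0.0,
            "locus1": geno[:, 0].astype(float),
            "locus2": geno[:, 1].astype(float),
        }
    )
    variants = pd.DataFrame(
        {
            "chrom": [1, 1],
            "snp_id": ["locus1", "locus2"],
            "pos": [1000, 2000],
            "allele_a": ["A", "A"],
            "allele_b": ["B", "B"],
        }
    )
    return GenotypeMatrix(samples, variants)
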
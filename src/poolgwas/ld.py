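"""Two-locus haplotype frequencies by EM and linkage-disequilibrium summaries.

With unphased biallelic genotypes, only double heterozygotes are phase
ambiguous; the EM algorithm resolves them by iterating between the expected
split of double heterozygotes into cis (11/00) and trans (10/01)
configurations and the implied haplotype frequencies.  D, D' and r^2 follow
from the converged frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = ["HaplotypeFreqs", "em_haplotypes", "ld_stats", "pairwise_ld"]


@dataclass
class HaplotypeFreqs:
    """Converged haplotype frequencies (p11, p10, p01, p00) for coded alleles
    at two loci, with the log-likelihood trace endpoint."""

    p11: float
    p10: float
    p01: float
    p00: float
    loglik: float
    n_iter: int
    converged: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p10, self.p01, self.p00])

    def __post_init__(self) -> None:
        p = self.as_array()
        if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be >= 0 and sum to 1")


def genotype_log_likelihood(counts: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under haplotype
    frequencies p = (p11, p10, p01, p00) with random mating."""
    p11, p10, p01, p00 = p
    probs = np.empty((3, 3))
    # genotype (g1, g2) = copies of coded allele at each locus
    probs[2, 2] = p11**2
    probs[2, 1] = 2 * p11 * p10
    probs[2, 0] = p10**2
    probs[1, 2] = 2 * p11 * p01
    probs[1, 1] = 2 * (p11 * p00 + p10 * p01)
    probs[1, 0] = 2 * p10 * p00
    probs[0, 2] = p01**2
    probs[0, 1] = 2 * p01 * p00
    probs[0, 0] = p00**2
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return float("-inf")
    return float(np.sum(counts[mask] * logp[mask]))


def _counts_from_table(counts: np.ndarray) -> np.ndarray:
    t = np.asarray(counts, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("expected a 3x3 genotype count table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("empty genotype table")
    return t


def em_haplotypes(
    counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> HaplotypeFreqs:
    """EM estimate of two-locus haplotype frequencies from a 3x3 genotype
    table (rows/cols indexed by copies 0/1/2 of the coded allele).

    Initialised at linkage equilibrium; the complete-data M-step counts
    haplotypes directly, with double heterozygotes split by the current
    cis/trans posterior.  Stops when the frequency change falls below
    ``tol``; non-convergence within ``max_iter`` returns the last iterate
    flagged ``converged=False``.
    """
    t = _counts_from_table(counts)
    n = t.sum()
    # allele counts at each locus (copies of the coded allele)
    g1 = t.sum(axis=1)  # index = copies at locus 1
    g2 = t.sum(axis=0)
    f1 = (2 * g1[2] + g1[1]) / (2 * n)
    f2 = (2 * g2[2] + g2[1]) / (2 * n)
    p = np.array(
        [f1 * f2, f1 * (1 - f2), (1 - f1) * f2, (1 - f1) * (1 - f2)], dtype=float
    )
    p = np.clip(p, 1e-12, None)
    p /= p.sum()

    # haplotype contributions of every genotype cell except the double het:
    # cell (i, j) with i,j = copies at locus1/locus2 contributes fixed counts
    fixed = np.zeros(4)
    contrib = {
        (2, 2): (2, 0, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 0): (0, 2, 0, 0),
        (1, 2): (1, 0, 1, 0),
        (1, 0): (0, 1, 0, 1),
        (0, 2): (0, 0, 2, 0),
        (0, 1): (0, 0, 1, 1),
        (0, 0): (0, 0, 0, 2),
    }
    for (i, j), vec in contrib.items():
        fixed += t[i, j] * np.asarray(vec, dtype=float)
    n_dh = t[1, 1]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        hap_counts = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        p_new = hap_counts / (2 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return HaplotypeFreqs(
        *p, loglik=genotype_log_likelihood(t, p), n_iter=it, converged=converged
    )


def ld_stats(h: HaplotypeFreqs) -> dict:
    """D, D' and r^2 from haplotype frequencies.

    D = p11 - f1*f2; r^2 = D^2 / (f1(1-f1)f2(1-f2)); D' = D/Dmax with
    Dmax = min(f1(1-f2), (1-f1)f2) for D >= 0 and min(f1*f2, (1-f1)(1-f2))
    for D < 0.  A monomorphic locus leaves the summaries undefined
    (``defined=False`` with NaNs).
    """
    f1 = h.p11 + h.p10
    f2 = h.p11 + h.p01
    var = f1 * (1 - f1) * f2 * (1 - f2)
    d = h.p11 - f1 * f2
    if var <= 0:
        return {"D": float("nan"), "Dprime": float("nan"), "r2": float("nan"),
                "defined": False}
    r2 = d * d / var
    d_max = min(f1 * (1 - f2), (1 - f1) * f2) if d >= 0 else min(f1 * f2, (1 - f1) * (1 - f2))
    dprime = 0.0 if d == 0 else d / d_max
    return {"D": float(d), "Dprime": float(dprime), "r2": float(r2), "defined": True}


def genotype_table_2loci(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> np.ndarray:
    """3x3 genotype count table for two SNPs, dropping pairwise-missing
    individuals."""
    ga = gm.genotype_values(snp_a)
    gb = gm.genotype_values(snp_b)
    ok = np.isfinite(ga) & np.isfinite(gb)
    t = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            t[i, j] = np.sum((ga[ok] == i) & (gb[ok] == j))
    return t


def pairwise_ld(
    gm: GenotypeMatrix, focal: str, window: int | None = None
) -> pd.DataFrame:
    """LD of the focal SNP with every other SNP (optionally within ``window``
    bp); one row per pair with D, D', r^2 and the sample count used."""
    v = gm.variants.set_index("snp_id")
    if focal not in v.index:
        raise KeyError(f"unknown focal SNP {focal!r}")
    fpos, fchrom = v.loc[focal, "pos"], v.loc[focal, "chrom"]
    rows = []
    for sid in gm.snp_ids:
        if sid == focal:
            continue
        if window is not None and (
            v.loc[sid, "chrom"] != fchrom or abs(v.loc[sid, "pos"] - fpos) > window
        ):
            continue
        t = genotype_table_2loci(gm, focal, sid)
        h = em_haplotypes(t)
        s = ld_stats(h)
        rows.append(
            {
                "snp_a": focal,
                "snp_b": sid,
                "D": s["D"],
                "Dprime": s["Dprime"],
                "r2": s["r2"],
                "n_used": int(t.sum()),
            }
        )
    return pd.DataFrame(rows)
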
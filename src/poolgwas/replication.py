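"""Individual-genotyping association statistics for replication panels.

Covers the statistics used on candidate-SNP panels after a pooled discovery
screen: per-SNP call-rate filtering, 2x2 allele-count tables, the allelic
chi-square test, odds ratios with Woolf 95% confidence intervals
(Haldane-Anscombe corrected when a cell is empty), the Cochran-Armitage
trend test, covariate-adjusted logistic association, the Bonferroni
threshold, fixed-effect inverse-variance-weighted meta-analysis of odds
ratios, and analytic power of the 1-df allelic test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix, risk_allele_frequency

__all__ = [
    "AlleleTable2x2",
    "MetaResult",
    "call_rate_filter",
    "allele_table",
    "allele_table_from_freqs",
    "allelic_or",
    "allelic_chi2",
    "trend_test",
    "genotype_counts",
    "adjusted_association",
    "bonferroni_threshold",
    "ivw_meta",
    "allelic_power",
]


@dataclass(frozen=True)
class AlleleTable2x2:
    """Allele counts: a/b = case risk/other, c/d = control risk/other.

    Counts may be non-integer when reconstructed from published frequencies.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")


@dataclass(frozen=True)
class MetaResult:
    or_value: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def call_rate_filter(
    gm: GenotypeMatrix, min_rate: float = 0.8
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep SNPs with call rate strictly above ``min_rate``."""
    removed = []
    for sid in gm.snp_ids:
        g = gm.genotype_values(sid)
        if np.isfinite(g).mean() <= min_rate:
            removed.append(sid)
    if not removed:
        return gm, []
    samples = gm.samples.drop(columns=removed)
    variants = gm.variants[~gm.variants["snp_id"].isin(removed)].reset_index(drop=True)
    return GenotypeMatrix(samples, variants), removed


def allele_table(
    gm: GenotypeMatrix, snp_id: str, risk_allele: str | None = None
) -> AlleleTable2x2:
    """Tally risk-allele counts in cases and controls for one SNP.

    Genotype codes count the coded (allele_b) allele; if ``risk_allele`` is
    allele_a the orientation is flipped.  Missing individuals are excluded.
    """
    if snp_id not in set(gm.snp_ids):
        raise KeyError(f"unknown SNP {snp_id!r}")
    row = gm.variants.set_index("snp_id").loc[snp_id]
    g = gm.genotype_values(snp_id)
    if risk_allele is None or risk_allele == row["allele_b"]:
        pass
    elif risk_allele == row["allele_a"]:
        g = 2.0 - g
    else:
        raise ValueError(f"risk allele {risk_allele!r} not among {row['allele_a']}/{row['allele_b']}")
    status = gm.samples["status"].to_numpy()
    ok = np.isfinite(g)
    case, ctrl = ok & (status == 1), ok & (status == 0)
    a = float(g[case].sum())
    b = float(2 * case.sum() - a)
    c = float(g[ctrl].sum())
    d = float(2 * ctrl.sum() - c)
    return AlleleTable2x2(a, b, c, d)


def allele_table_from_freqs(
    maf_case: float, n_case: int, maf_control: float, n_control: int
) -> AlleleTable2x2:
    """Reconstruct allele counts from published frequencies and sample sizes
    (counts are generally non-integer)."""
    return AlleleTable2x2(
        2 * n_case * maf_case,
        2 * n_case * (1 - maf_case),
        2 * n_control * maf_control,
        2 * n_control * (1 - maf_control),
    )


def allelic_or(
    table: AlleleTable2x2, orient_case_enriched: bool = False
) -> tuple[float, float, float]:
    """Allelic odds ratio with Woolf 95% CI.

    OR = (a/b)/(c/d); CI = exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).  If any
    cell is zero all cells get the Haldane-Anscombe +0.5.  With
    ``orient_case_enriched`` the table is flipped, if needed, so the reported
    OR is >= 1 (the convention some published rows use when the designated
    risk allele is depleted in cases).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("degenerate 2x2 table (empty margin)")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if orient_case_enriched and (a / b) < (c / d):
        a, b, c, d = b, a, d, c
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        math.exp(log_or),
        math.exp(log_or - 1.96 * se),
        math.exp(log_or + 1.96 * se),
    )


def allelic_chi2(table: AlleleTable2x2) -> tuple[float, float]:
    """1-df Pearson chi-square of allele counts, no continuity correction."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        raise ValueError("degenerate 2x2 table (zero margin)")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def genotype_counts(gm: GenotypeMatrix, snp_id: str) -> np.ndarray:
    """2x3 table of genotype counts: rows case/control, columns 0/1/2 copies
    of the coded allele; missing dropped."""
    g = gm.genotype_values(snp_id)
    status = gm.samples["status"].to_numpy()
    ok = np.isfinite(g)
    out = np.zeros((2, 3))
    for i, grp in enumerate((1, 0)):
        sel = ok & (status == grp)
        for k in range(3):
            out[i, k] = np.sum(g[sel] == k)
    return out


def trend_test(counts: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test with scores (0, 1, 2).

    ``counts`` is the 2x3 case/control-by-genotype table.  Returns the signed
    z statistic and the two-sided p-value.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 case/control x genotype table")
    n = t.sum()
    r = t[0].sum()  # cases
    col = t.sum(axis=0)
    if n == 0 or r == 0 or r == n:
        raise ValueError("degenerate table: no cases or no controls")
    scores = np.array([0.0, 1.0, 2.0])
    stat = np.dot(scores, t[0]) - r / n * np.dot(scores, col)
    var = (
        r * (n - r) / n * (np.dot(scores**2, col) / n - (np.dot(scores, col) / n) ** 2)
    )
    if var <= 0:
        raise ValueError("degenerate table: zero trend variance")
    z = float(stat / math.sqrt(var))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def adjusted_association(
    gm: GenotypeMatrix, snp_id: str, covariates: tuple[str, ...] = ("sex", "age")
) -> dict:
    """Wald p for the additive genotype term in a logistic model with
    covariates, fit by IRLS (tol 1e-8, <= 50 iterations).

    Returns ``{"p": ..., "beta": ..., "converged": bool}``; separation or
    non-convergence yields ``converged=False`` with NaN p rather than a
    crash.  A constant genotype column is reported the same way.
    """
    import statsmodels.api as sm

    g = gm.genotype_values(snp_id)
    cov = gm.samples[list(covariates)].to_numpy(dtype=float)
    y = gm.samples["status"].to_numpy(dtype=float)
    ok = np.isfinite(g) & np.isfinite(cov).all(axis=1)
    g, cov, y = g[ok], cov[ok], y[ok]
    if np.all(g == g[0]):
        return {"p": float("nan"), "beta": float("nan"), "converged": False}
    X = sm.add_constant(np.column_stack([g, cov]))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=50, tol=1e-8)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("IRLS did not converge")
        return {"p": float(fit.pvalues[1]), "beta": float(fit.params[1]), "converged": True}
    except Exception:
        return {"p": float("nan"), "beta": float("nan"), "converged": False}


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Per-test significance threshold alpha/m, returned exact and rounded to
    two significant figures (e.g. 0.05/9 -> 0.0056)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    exact = alpha / m
    rounded = float(f"{exact:.2g}")
    return exact, rounded


def ivw_meta(studies) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis of odds ratios.

    Each study is (or_value, ci_low, ci_high) with a 95% CI, or
    (log_or, se) when exactly two numbers are given and the first may be
    negative.  Pooled log-odds = sum(w_i b_i)/sum(w_i), w_i = 1/SE_i^2.
    A single study is returned unchanged (recomputed from its own SE).
    """
    betas, ses = [], []
    for s in studies:
        if len(s) == 2:
            beta, se = float(s[0]), float(s[1])
        else:
            orv, lo, hi = (float(x) for x in s)
            if not 0 < lo < orv < hi:
                raise ValueError(f"inconsistent study summary {s!r}")
            beta = math.log(orv)
            se = (math.log(hi) - math.log(lo)) / (2 * 1.96)
        if se <= 0:
            raise ValueError("nonpositive standard error")
        betas.append(beta)
        ses.append(se)
    if not betas:
        raise ValueError("no studies")
    w = 1.0 / np.asarray(ses) ** 2
    beta_pooled = float(np.sum(w * betas) / np.sum(w))
    se_pooled = float(1.0 / math.sqrt(np.sum(w)))
    z = beta_pooled / se_pooled
    return MetaResult(
        or_value=math.exp(beta_pooled),
        ci_low=math.exp(beta_pooled - 1.96 * se_pooled),
        ci_high=math.exp(beta_pooled + 1.96 * se_pooled),
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


def allelic_power(
    n_case: int, n_control: int, maf_control: float, or_value: float, alpha: float
) -> float:
    """Analytic power of the 1-df allelic chi-square test.

    The implied case frequency is f1 = OR*f/(1-f+OR*f); the test's
    noncentrality parameter is (f1-f0)^2 / (pbar(1-pbar)(1/m1 + 1/m2)) with
    allele counts m = 2n and pbar the count-weighted pooled frequency, and
    power is the upper tail of the noncentral chi-square at the alpha
    critical value.
    """
    if not (0 < maf_control < 1 and or_value > 0 and 0 < alpha < 1):
        raise ValueError("parameters out of range")
    if n_case < 1 or n_control < 1:
        raise ValueError("sample sizes must be >= 1")
    f1 = float(risk_allele_frequency(maf_control, or_value))
    f0 = maf_control
    m1, m2 = 2.0 * n_case, 2.0 * n_control
    pbar = (m1 * f1 + m2 * f0) / (m1 + m2)
    ncp = (f1 - f0) ** 2 / (pbar * (1 - pbar) * (1 / m1 + 1 / m2))
    crit = stats.chi2.ppf(1 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def stage_result(
    gm: GenotypeMatrix,
    risk_alleles: dict[str, str] | None = None,
    covariates: tuple[str, ...] | None = ("sex", "age"),
    min_call_rate: float = 0.8,
) -> pd.DataFrame:
    """Per-SNP replication summary table: MAFs, allelic chi-square p, trend
    p, optional covariate-adjusted p, OR and 95% CI."""
    gm, removed = call_rate_filter(gm, min_call_rate)
    rows = []
    for sid in gm.snp_ids:
        risk = (risk_alleles or {}).get(sid)
        tab = allele_table(gm, sid, risk)
        orv, lo, hi = allelic_or(tab)
        chi2, p_allelic = allelic_chi2(tab)
        counts = genotype_counts(gm, sid)
        try:
            _, p_trend = trend_test(counts)
        except ValueError:
            p_trend = float("nan")
        row = {
            "snp_id": sid,
            "maf_case": tab.a / (tab.a + tab.b),
            "maf_control": tab.c / (tab.c + tab.d),
            "p_allelic": p_allelic,
            "p_trend": p_trend,
            "or_value": orv,
            "ci_low": lo,
            "ci_high": hi,
        }
        if covariates:
            row["p_adjusted"] = adjusted_association(gm, sid, covariates)["p"]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["removed_low_call_rate"] = removed
    return out
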
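"""Pooled case-control association: combined Z, empirical null, genomic control.

The per-batch statistic contrasts estimated pool frequencies:

    z = (f_case - f_ctrl) / sqrt( fbar(1-fbar) (1/(2 n_case) + 1/(2 n_ctrl))
                                  + Ve_case + Ve_ctrl )

where fbar is the n-weighted pooled frequency (so with Ve = 0 this is the
textbook two-proportion z-test) and Ve is each pool's squared standard error
of the replicate mean (replicate variance / replicate count) — the array
measurement component that individual-genotyping studies do not have.

Because the variance model is approximate, the null scale is calibrated
empirically from the genome-wide panel: the SD of z is estimated as the
slope of the QQ line through the first and third quartiles (IQR divided by
twice the normal 75% deviate), z is standardised per batch, batches are
combined by sample-size-weighted Stouffer, and residual inflation is removed
by genomic control (lambda = median chi-square of a random SNP subset over
0.4549, floored at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PoolDesign

__all__ = [
    "AssocResult",
    "pooled_z",
    "estimate_null_sd",
    "combine_batches",
    "genomic_control",
    "run_discovery",
]

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45494
_Q75 = float(stats.norm.ppf(0.75))  # 0.67449


@dataclass
class AssocResult:
    """Discovery-stage association results, sorted by adjusted p-value.

    ``table`` columns: snp_id, chrom, pos, z_b1, z_b2 (NaN if single batch),
    z_comb, chi2, p_raw, chi2_gc, p_gc.  ``null_sd`` maps batch -> estimated
    empirical-null SD; ``lambda_gc`` is the genomic inflation factor.
    """

    table: pd.DataFrame
    null_sd: dict[int, float]
    lambda_gc: float


def pooled_z(f_case, f_control, n_case, n_control, var_e_case=0.0, var_e_control=0.0):
    """Pooled-frequency association z-score (vectorised).

    ``var_e_*`` are the squared standard errors of each pool's replicate-mean
    frequency; with both zero this reduces to the two-proportion z-test.
    """
    fc = np.asarray(f_case, dtype=float)
    fk = np.asarray(f_control, dtype=float)
    ve_c = np.asarray(var_e_case, dtype=float)
    ve_k = np.asarray(var_e_control, dtype=float)
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample counts must be positive")
    if (ve_c < 0).any() or (ve_k < 0).any():
        raise ValueError("error variances must be >= 0")
    m_c, m_k = 2.0 * n_case, 2.0 * n_control
    fbar = (m_c * fc + m_k * fk) / (m_c + m_k)
    denom2 = fbar * (1.0 - fbar) * (1.0 / m_c + 1.0 / m_k) + ve_c + ve_k
    if (denom2 <= 0).any():
        raise ZeroDivisionError("zero variance in pooled z denominator")
    out = (fc - fk) / np.sqrt(denom2)
    return float(out) if out.ndim == 0 else out


def estimate_null_sd(z_values) -> float:
    """Empirical-null SD as the quartile slope of the QQ plot.

    IQR(z) / (2 * 0.6745): the slope of the line through the first and third
    quartiles against standard-normal quantiles.  Robust to true association
    signals, which live in the tails.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 100:
        raise ValueError("need >= 100 finite z values to estimate the null SD")
    q25, q75 = np.percentile(z, [25, 75])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("degenerate z distribution (zero IQR)")
    return float(iqr / (2.0 * _Q75))


def empirical_null(z_values) -> tuple[float, float]:
    """Location and scale of the empirical null: the line through the first
    and third QQ quartile points.

    Returns (center, sd) with center = (q25 + q75)/2 and sd the quartile
    slope of :func:`estimate_null_sd`.  Pooled-array panels need the location
    term too: per-array normalisation noise shifts every frequency of an
    array coherently, giving all z's of a batch a small common offset.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    q25, q75 = np.percentile(z, [25, 75])
    return float((q25 + q75) / 2.0), estimate_null_sd(z)


def combine_batches(z1, n1, z2=None, n2=None):
    """Stouffer combination with weights sqrt(effective sample size).

    z = (w1 z1 + w2 z2) / sqrt(w1^2 + w2^2); with a single batch the input is
    returned unchanged.  Element-wise NaNs in ``z2`` fall back to ``z1``.
    """
    z1 = np.asarray(z1, dtype=float)
    if z2 is None:
        return float(z1) if z1.ndim == 0 else z1
    if n1 <= 0 or n2 is None or n2 <= 0:
        raise ValueError("effective sample sizes must be positive")
    z2 = np.asarray(z2, dtype=float)
    w1, w2 = np.sqrt(n1), np.sqrt(n2)
    comb = (w1 * z1 + w2 * z2) / np.hypot(w1, w2)
    out = np.where(np.isnan(z2), z1, comb)
    return float(out) if out.ndim == 0 else out


def genomic_control(
    chi2_values, n_random: int = 20_000, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Genomic-control inflation factor and adjusted statistics.

    lambda is the median chi-square of ``n_random`` SNPs sampled without
    replacement, divided by the 1-df null median 0.4549 and floored at 1;
    every statistic is divided by lambda.
    """
    chi2 = np.asarray(chi2_values, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty chi-square collection")
    if (chi2 < 0).any():
        raise ValueError("chi-square values must be >= 0")
    n_random = min(int(n_random), chi2.size)
    if n_random < 1:
        raise ValueError("empty random subset")
    rng = np.random.default_rng(seed)
    subset = rng.choice(chi2, size=n_random, replace=False)
    lam = max(1.0, float(np.median(subset)) / _CHI2_1_MEDIAN)
    return lam, chi2 / lam


def _effective_n(n_case: float, n_control: float) -> float:
    return n_case * n_control / (n_case + n_control)


def _batch_z(freq_table: pd.DataFrame, batch: int) -> tuple[pd.Series, float]:
    """Per-SNP z for one batch from the QC'd pool-frequency table."""
    sub = freq_table[freq_table["batch"] == batch]
    sides = {}
    n_subjects = {}
    for group in ("case", "control"):
        g = sub[sub["group"] == group]
        if g.empty:
            raise ValueError(f"batch {batch} lacks {group} pools")
        n_by_pool = g.groupby("pool_id")["n_subjects"].first()
        w = n_by_pool / n_by_pool.sum()
        pivot_f = g.pivot(index="snp_id", columns="pool_id", values="f_hat")
        pivot_ve = g.pivot(index="snp_id", columns="pool_id", values="var_e")
        sides[group] = (
            (pivot_f * w).sum(axis=1),
            (pivot_ve * w**2).sum(axis=1),
        )
        n_subjects[group] = float(n_by_pool.sum())
    f_c, ve_c = sides["case"]
    f_k, ve_k = sides["control"]
    common = f_c.index.intersection(f_k.index)
    z = pooled_z(
        f_c.loc[common],
        f_k.loc[common],
        n_subjects["case"],
        n_subjects["control"],
        ve_c.loc[common],
        ve_k.loc[common],
    )
    return pd.Series(z, index=common), _effective_n(n_subjects["case"], n_subjects["control"])


def run_discovery(
    qc_result,
    design: PoolDesign,
    n_random: int = 20_000,
    seed: int = 0,
) -> AssocResult:
    """Full discovery-stage association over a QC'd pool-frequency table.

    Per batch: pooled z -> divide by the batch's empirical-null SD; then
    Stouffer combination across batches, chi-square = z^2, genomic control,
    and two-sided p-values.  ``qc_result`` is a :class:`poolgwas.qc.QCResult`
    (or its table).
    """
    table = qc_result.table if hasattr(qc_result, "table") else qc_result
    n_map = {p.pool_id: p.n_subjects for p in design.pools}
    # Array-measurement variance is a per-pool property of the platform, so
    # the replicate-scatter estimate is pooled across SNPs: per-SNP 2-df
    # variance estimates would give the z statistic t-like tails.
    pool_var_e = (table["f_var"] / table["n_reps"]).groupby(table["pool_id"]).mean()
    table = table.assign(
        n_subjects=table["pool_id"].map(n_map),
        var_e=table["pool_id"].map(pool_var_e),
    )
    if table["n_subjects"].isna().any():
        missing = table.loc[table["n_subjects"].isna(), "pool_id"].unique()
        raise KeyError(f"pools absent from design: {list(missing)}")

    batches = sorted(table["batch"].unique())
    z_std: dict[int, pd.Series] = {}
    n_eff: dict[int, float] = {}
    null_sd: dict[int, float] = {}
    for b in batches:
        z_raw, ne = _batch_z(table, b)
        center, sd = empirical_null(z_raw)
        null_sd[b] = sd
        z_std[b] = (z_raw - center) / sd
        n_eff[b] = ne

    b1 = batches[0]
    if len(batches) == 1:
        z_comb = z_std[b1]
        z_b2 = pd.Series(np.nan, index=z_comb.index)
    else:
        b2 = batches[1]
        common = z_std[b1].index.intersection(z_std[b2].index)
        z_comb = pd.Series(
            combine_batches(
                z_std[b1].loc[common].to_numpy(),
                n_eff[b1],
                z_std[b2].loc[common].to_numpy(),
                n_eff[b2],
            ),
            index=common,
        )
        z_b2 = z_std[b2].reindex(z_comb.index)

    chi2 = z_comb**2
    lam, chi2_gc = genomic_control(chi2.to_numpy(), n_random=n_random, seed=seed)
    coords = (
        table[["snp_id", "chrom", "pos"]]
        .drop_duplicates("snp_id")
        .set_index("snp_id")
        .reindex(z_comb.index)
    )
    out = pd.DataFrame(
        {
            "snp_id": z_comb.index,
            "chrom": coords["chrom"].to_numpy(),
            "pos": coords["pos"].to_numpy(),
            "z_b1": z_std[b1].reindex(z_comb.index).to_numpy(),
            "z_b2": z_b2.to_numpy(),
            "z_comb": z_comb.to_numpy(),
            "chi2": chi2.to_numpy(),
            "p_raw": 2.0 * stats.norm.sf(np.abs(z_comb.to_numpy())),
            "chi2_gc": chi2_gc,
            "p_gc": stats.chi2.sf(chi2_gc, 1),
        }
    ).sort_values(["p_gc", "snp_id"], kind="mergesort").reset_index(drop=True)
    return AssocResult(out, null_sd, lam)


def qq_plot(z_values, path, null_sd: float | None = None):
    """QQ plot of observed z quantiles against standard-normal quantiles,
    with the quartile line Y = sd * X (plumbing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = np.sort(np.asarray(z_values, dtype=float))
    q = stats.norm.ppf((np.arange(1, z.size + 1) - 0.5) / z.size)
    sd = estimate_null_sd(z) if null_sd is None else null_sd
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(q, z, ".", ms=2)
    ax.plot(q, sd * q, "r-", lw=1, label=f"Y = {sd:.3f} X")
    ax.set_xlabel("standard normal quantiles")
    ax.set_ylabel("observed z quantiles")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manhattan_plot(assoc: AssocResult, path, p_column: str = "p_gc"):
    """Genome-wide -log10(p) scatter ordered by chromosome and position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = assoc.table.sort_values(["chrom", "pos"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(8, 3))
    colors = t["chrom"].astype(int) % 2
    ax.scatter(t.index, -np.log10(t[p_column]), c=colors, cmap="tab10", s=4)
    ax.set_xlabel("SNPs (genome order)")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
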
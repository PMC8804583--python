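"""Quality control and allele-frequency estimation for pooled arrays.

The estimated frequency of the coded allele at each probe is
``f = x_raw / (x_raw + y_raw)`` after per-array channel normalisation.  A
four-stage QC cascade then runs, in this order:

1. replicate correlation  — replicate arrays whose frequency estimates
   correlate poorly (Pearson R < 0.99 by default) with the other replicates
   of their pool are discarded;
2. low intensity          — SNPs in the lowest 5% of total x+y intensity are
   removed;
3. replicate divergence   — SNPs whose replicate frequencies span more than
   5% within any pool are removed;
4. minor-allele frequency — SNPs with control-pool MAF below 1% are removed.

Surviving per-pool frequencies are the means over retained replicates.
Every removal is recorded with its reason, and each filter only removes —
it never alters surviving values — so the cascade is idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "QCResult",
    "estimate_frequency",
    "normalize_channels",
    "replicate_correlation_filter",
    "low_intensity_filter",
    "divergence_filter",
    "maf_filter",
    "pool_frequencies",
    "frequency_bias_report",
]


@dataclass(frozen=True)
class QCConfig:
    r_min: float = 0.99
    low_intensity_fraction: float = 0.05
    max_divergence: float = 0.05
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("r_min", "low_intensity_fraction", "max_divergence", "maf_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class QCResult:
    """Outcome of the QC cascade.

    ``table``: per (snp_id, pool_id) estimated frequency ``f_hat``, replicate
    count, replicate variance (``f_var``, ddof=1; 0 with one replicate),
    total intensity, plus pool group/batch labels.
    ``removed``: per removed SNP the stage responsible
    (low_intensity / divergent / low_maf).
    ``dropped_replicates``: (pool_id, replicate) arrays discarded by the
    correlation filter.  ``log``: human-readable removal lines.
    """

    table: pd.DataFrame
    removed: pd.DataFrame
    dropped_replicates: list[tuple[str, int]]
    config: QCConfig
    log: list[str] = field(default_factory=list)


def estimate_frequency(x_raw, y_raw):
    """Coded-allele frequency from two-channel intensities: x / (x + y)."""
    x = np.asarray(x_raw, dtype=float)
    y = np.asarray(y_raw, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("intensities must be non-negative")
    total = x + y
    if (total == 0).any():
        raise ValueError("undefined frequency: x_raw + y_raw = 0")
    out = x / total
    return float(out) if out.ndim == 0 else out


def normalize_channels(panel: pd.DataFrame) -> pd.DataFrame:
    """Equalise channel medians per replicate array.

    For each (pool_id, replicate) array the x channel is rescaled by
    median(y)/median(x) so the two channel medians match; y is untouched and
    row order is preserved.
    """
    if panel.empty:
        raise ValueError("empty intensity panel")
    out = panel.copy()
    for (pool_id, rep), idx in out.groupby(["pool_id", "replicate"]).groups.items():
        mx = out.loc[idx, "x_raw"].median()
        my = out.loc[idx, "y_raw"].median()
        if mx == 0 or my == 0:
            raise ValueError(
                f"all-zero channel median on array pool={pool_id} replicate={rep}"
            )
        out.loc[idx, "x_raw"] = out.loc[idx, "x_raw"] * (my / mx)
    return out


def _replicate_freq_matrix(panel: pd.DataFrame, pool_id: str) -> pd.DataFrame:
    sub = panel[panel["pool_id"] == pool_id]
    freqs = estimate_frequency(sub["x_raw"].to_numpy(), sub["y_raw"].to_numpy())
    return (
        sub.assign(f=freqs)
        .pivot(index="snp_id", columns="replicate", values="f")
        .sort_index()
    )


def replicate_correlation_filter(
    panel: pd.DataFrame, r_min: float = 0.99
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Discard replicate arrays that do not track their pool-mates.

    Within each pool, pairwise Pearson correlations of per-SNP frequency
    estimates are computed between replicates.  While any replicate's mean
    pairwise correlation falls below ``r_min``, the worst replicate is
    removed and correlations recomputed (greedy), stopping when all remaining
    replicates pass or only one is left — a single bad array therefore never
    condemns its good pool-mates.
    """
    dropped: list[tuple[str, int]] = []
    for pool_id in panel["pool_id"].unique():
        mat = _replicate_freq_matrix(panel, pool_id)
        reps = list(mat.columns)
        if len(reps) == 0:
            raise ValueError(f"pool {pool_id} has no replicates")
        while len(reps) >= 2:
            corr = mat[reps].corr(method="pearson")
            mean_r = (corr.sum(axis=0) - 1.0) / (len(reps) - 1)
            if (mean_r >= r_min).all():
                break
            worst = mean_r.idxmin()
            reps.remove(worst)
            dropped.append((pool_id, int(worst)))
    if dropped:
        drop_keys = set(dropped)
        keep = ~panel.apply(
            lambda r: (r["pool_id"], int(r["replicate"])) in drop_keys, axis=1
        )
        panel = panel[keep].reset_index(drop=True)
    return panel, dropped


def low_intensity_filter(
    panel: pd.DataFrame, fraction: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Remove the floor(fraction * n_snps) SNPs with the lowest total
    x_raw + y_raw over retained replicates; ties broken by snp_id."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    totals = (
        (panel["x_raw"] + panel["y_raw"])
        .groupby(panel["snp_id"])
        .sum()
        .rename("total")
        .reset_index()
        .sort_values(["total", "snp_id"], kind="mergesort")
    )
    k = math.floor(fraction * len(totals))
    removed = sorted(totals["snp_id"].head(k))
    return panel[~panel["snp_id"].isin(removed)].reset_index(drop=True), removed


def divergence_filter(
    panel: pd.DataFrame, max_divergence: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Remove SNPs whose replicate frequencies span more than
    ``max_divergence`` (strict) within any single pool."""
    f = estimate_frequency(panel["x_raw"].to_numpy(), panel["y_raw"].to_numpy())
    span = (
        panel.assign(f=f)
        .groupby(["snp_id", "pool_id"])["f"]
        .agg(lambda s: s.max() - s.min())
    )
    bad = span[span > max_divergence].index.get_level_values("snp_id")
    removed = sorted(set(bad))
    return panel[~panel["snp_id"].isin(removed)].reset_index(drop=True), removed


def maf_filter(
    panel: pd.DataFrame, maf_min: float = 0.01
) -> tuple[pd.DataFrame, list[str]]:
    """Remove SNPs with control-pool MAF strictly below ``maf_min``.

    The control frequency is the mean over control pools of each pool's mean
    replicate frequency; MAF = min(f, 1-f).
    """
    ctrl = panel[panel["group"] == "control"]
    if ctrl.empty:
        raise ValueError("no control pools in panel")
    f = estimate_frequency(ctrl["x_raw"].to_numpy(), ctrl["y_raw"].to_numpy())
    pool_mean = ctrl.assign(f=f).groupby(["snp_id", "pool_id"])["f"].mean()
    fbar = pool_mean.groupby("snp_id").mean()
    maf = np.minimum(fbar, 1.0 - fbar)
    removed = sorted(maf[maf < maf_min].index)
    return panel[~panel["snp_id"].isin(removed)].reset_index(drop=True), removed


def pool_frequencies(
    panel: pd.DataFrame, config: QCConfig | None = None, normalize: bool = True
) -> QCResult:
    """Run the full QC cascade and average surviving replicate frequencies.

    Stage order is fixed: channel normalisation (optional here; a
    pre-normalised panel may pass ``normalize=False``), replicate
    correlation, low intensity, divergence, control MAF.
    """
    config = config or QCConfig()
    log: list[str] = []
    if normalize:
        panel = normalize_channels(panel)
    panel, dropped = replicate_correlation_filter(panel, config.r_min)
    for pool_id, rep in dropped:
        log.append(f"replicate_dropped\tpool={pool_id}\treplicate={rep}\tR<{config.r_min}")
    removal_frames = []
    stages = (
        ("low_intensity", low_intensity_filter, config.low_intensity_fraction),
        ("divergent", divergence_filter, config.max_divergence),
        ("low_maf", maf_filter, config.maf_min),
    )
    for stage, fn, param in stages:
        panel, removed = fn(panel, param)
        removal_frames.append(pd.DataFrame({"snp_id": removed, "reason": stage}))
        log.extend(f"snp_removed\t{s}\treason={stage}" for s in removed)
    removed_df = pd.concat(removal_frames, ignore_index=True)

    f = estimate_frequency(panel["x_raw"].to_numpy(), panel["y_raw"].to_numpy())
    work = panel.assign(f=f, total=panel["x_raw"] + panel["y_raw"])
    table = (
        work.groupby(["snp_id", "pool_id"], as_index=False)
        .agg(
            chrom=("chrom", "first"),
            pos=("pos", "first"),
            group=("group", "first"),
            batch=("batch", "first"),
            f_hat=("f", "mean"),
            f_var=("f", lambda s: s.var(ddof=1) if len(s) > 1 else 0.0),
            n_reps=("f", "size"),
            total_intensity=("total", "sum"),
        )
        .sort_values(["snp_id", "pool_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return QCResult(table, removed_df, dropped, config, log)


def frequency_bias_report(
    freq_table: pd.DataFrame, truth
) -> tuple[pd.DataFrame, float]:
    """Signed estimation error of each pool frequency against ground truth.

    Returns the per-(snp, pool) table with an ``error = f_hat - f_true``
    column (truth taken from the pool's group) and the mean bias.  Raises if
    the table contains SNPs absent from the truth panel.
    """
    v = truth.variants.set_index("snp_id")
    unknown = set(freq_table["snp_id"]) - set(v.index)
    if unknown:
        raise KeyError(f"SNPs missing from truth panel: {sorted(unknown)[:5]}")
    f_true = np.where(
        freq_table["group"] == "case",
        v.loc[freq_table["snp_id"], "f_case"],
        v.loc[freq_table["snp_id"], "f_control"],
    )
    out = freq_table.assign(f_true=f_true, error=freq_table["f_hat"] - f_true)
    return out, float(out["error"].mean())
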
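"""Readers, writers and run configuration shared across the pipeline.

All tables travel as TSV.  Schemas:

* intensity panel: ``snp_id chrom pos pool_id group batch replicate x_raw y_raw``
* truth panel:     ``snp_id chrom pos allele_a allele_b f_control or_risk``
* genotypes:       rows = samples, columns ``sample_id status sex age <snp_id>...``
  with 0/1/2 codes and ``NA`` for missing, plus a PLINK-style ``.map``
  sidecar (``chrom snp_id 0 pos``, 1-based positions).

Reports are rendered deterministically (fixed column order; frequencies to
4 dp, odds ratios to 2 dp, p-values in 3-sf scientific notation) so repeated
runs with the same seed diff clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .qc import QCConfig
from .simulate import GenotypeMatrix, PoolDesign, PoolSpec, TruthPanel, default_design

__all__ = [
    "RunConfig",
    "write_intensity_panel",
    "read_intensity_panel",
    "write_truth_panel",
    "read_truth_panel",
    "write_genotype_table",
    "read_genotype_table",
    "write_report",
]

_GENOTYPE_META = ["sample_id", "status", "sex", "age"]


@dataclass
class RunConfig:
    """One YAML document driving a full reproducible run."""

    seed: int = 0
    n_snps: int = 20_000
    qc: QCConfig = field(default_factory=QCConfig)
    design: PoolDesign = field(default_factory=default_design)
    n_random: int = 20_000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("seed", "n_snps", "n_random", "alpha"):
            if key in raw:
                kwargs[key] = raw[key]
        if "qc" in raw:
            kwargs["qc"] = QCConfig(**raw["qc"])
        if "design" in raw:
            d = dict(raw["design"])
            if "pools" in d:
                d["pools"] = [PoolSpec(**p) for p in d["pools"]]
            kwargs["design"] = (
                default_design(**{k: v for k, v in d.items() if k != "pools"})
                if "pools" not in d
                else PoolDesign(**d)
            )
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# intensity / truth panels


def write_intensity_panel(panel: pd.DataFrame, path) -> None:
    cols = ["snp_id", "chrom", "pos", "pool_id", "group", "batch", "replicate", "x_raw", "y_raw"]
    panel[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_intensity_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    missing = {"snp_id", "pool_id", "replicate", "x_raw", "y_raw"} - set(panel.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    return panel


def write_truth_panel(truth: TruthPanel, path) -> None:
    cols = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "f_control", "or_risk"]
    truth.variants[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_truth_panel(path) -> TruthPanel:
    from .simulate import risk_allele_frequency

    v = pd.read_csv(path, sep="\t")
    v["f_case"] = risk_allele_frequency(v["f_control"], v["or_risk"])
    return TruthPanel(v)


# ---------------------------------------------------------------------------
# genotypes


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    """TSV of samples x SNPs plus a PLINK-style .map sidecar."""
    path = Path(path)
    df = gm.samples.copy()
    for sid in gm.snp_ids:
        df[sid] = df[sid].map(lambda g: "NA" if pd.isna(g) else str(int(g)))
    df.to_csv(path, sep="\t", index=False)
    sidecar = gm.variants.assign(cm=0)[["chrom", "snp_id", "cm", "pos"]]
    sidecar.to_csv(path.with_suffix(".map"), sep="\t", index=False, header=False)


def read_genotype_table(path) -> GenotypeMatrix:
    """Read a genotype TSV, validating 0/1/2/NA codes (errors name the
    offending line) and picking up the ``.map`` sidecar when present."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENOTYPE_META) - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    snp_cols = [c for c in df.columns if c not in _GENOTYPE_META]
    for col in snp_cols:
        vals = df[col]
        bad = ~vals.isin(["0", "1", "2", "NA"]) & vals.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"invalid genotype code {vals[bad].iloc[0]!r} at line {line}, column {col}"
            )
        df[col] = vals.replace("NA", np.nan).astype(float)
    df["status"] = df["status"].astype(int)
    df["sex"] = df["sex"].astype(int)
    df["age"] = df["age"].astype(float)
    map_path = path.with_suffix(".map")
    if map_path.exists():
        sidecar = pd.read_csv(
            map_path, sep="\t", header=None, names=["chrom", "snp_id", "cm", "pos"]
        )
        variants = sidecar[["chrom", "snp_id", "pos"]].copy()
    else:
        variants = pd.DataFrame({"chrom": 0, "snp_id": snp_cols, "pos": 0})
    variants["allele_a"] = "A"
    variants["allele_b"] = "B"
    return GenotypeMatrix(df, variants.reset_index(drop=True))


def call_rates(gm: GenotypeMatrix) -> pd.Series:
    return pd.Series(
        {sid: float(np.isfinite(gm.genotype_values(sid)).mean()) for sid in gm.snp_ids},
        name="call_rate",
    )


# ---------------------------------------------------------------------------
# reports


_FREQ_COLS = {"maf_case", "maf_control", "f_hat", "f_control", "f_case", "f_true", "error"}
_OR_COLS = {"or_value", "ci_low", "ci_high"}
_P_COLS = {"p", "p_raw", "p_gc", "p_allelic", "p_trend", "p_adjusted"}


def _format_value(col: str, v):
    if pd.isna(v):
        return "NA"
    if col in _FREQ_COLS:
        return f"{v:.4f}"
    if col in _OR_COLS:
        return f"{v:.2f}"
    if col in _P_COLS:
        return f"{v:.2e}"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_report(results: pd.DataFrame, path, log_lines: list[str] | None = None) -> None:
    """Deterministic TSV rendering with the module's precision rules, plus an
    optional ``.log`` companion."""
    path = Path(path)
    out = results.copy()
    for col in out.columns:
        out[col] = out[col].map(lambda v, c=col: _format_value(c, v))
    out.to_csv(path, sep="\t", index=False)
    if log_lines is not None:
        path.with_suffix(path.suffix + ".log").write_text("\n".join(log_lines) + "\n")
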
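"""Relative quantification of qPCR expression by the comparative-Ct method.

RQ = 2^(-ddCt) with dCt = Ct_target - Ct_reference per sample and
ddCt = dCt_treated - dCt_calibrator.  Duplicate wells are averaged on the Ct
scale before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import math

__all__ = ["CtRecord", "relative_quantity"]


@dataclass(frozen=True)
class CtRecord:
    """Cycle-threshold measurements for one sample; Ct values are the means
    of replicate wells (use :meth:`from_wells` to average duplicates)."""

    sample_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")

    @classmethod
    def from_wells(cls, sample_id, ct_target_wells, ct_reference_wells) -> "CtRecord":
        return cls(sample_id, fmean(ct_target_wells), fmean(ct_reference_wells))

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_quantity(treated: CtRecord, calibrator: CtRecord) -> float:
    """Fold change of the target gene in ``treated`` relative to
    ``calibrator``, normalised to the reference gene: 2^(-ddCt)."""
    ddct = treated.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)
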
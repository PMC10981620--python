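"""Relative quantitation of qPCR by the 2^-ddCt method.

dCt = mean(Ct_target - Ct_reference) within each group; ddCt is the
treatment-minus-control difference of group means; the fold change is
2^-ddCt. One PCR cycle of difference therefore corresponds to a
two-fold change in relative quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CtRecord:
    sample_id: str
    ct_target: float
    ct_reference: float
    group: str  # "treatment" or "control"

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def _mean_delta_ct(records) -> float:
    records = list(records)
    if not records:
        raise ValueError("empty Ct record group")
    return float(np.mean([r.delta_ct for r in records]))


def relative_quantity(treatment, control) -> float:
    """Fold change 2^-ddCt of treatment relative to control."""
    ddct = _mean_delta_ct(treatment) - _mean_delta_ct(control)
    return float(2.0 ** (-ddct))


def per_sample_fold_changes(treatment, control) -> dict:
    """Per-sample 2^-(dCt_sample - mean dCt_control) for the treatment group."""
    ref = _mean_delta_ct(control)
    return {r.sample_id: float(2.0 ** (-(r.delta_ct - ref))) for r in treatment}
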
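"""Phenotype and qPCR validation arithmetic.

Small, formula-level utilities: percent change of a trait under treatment,
Pearson correlation with its two-sided t test (cor.test semantics), and
relative expression by the comparative threshold cycle (2^-ddCT) method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["QpcrRecord", "percent_change", "pearson_r", "ddct_fold_change"]


def percent_change(control_mean: float, treatment_mean: float) -> float:
    """Signed percent change relative to control (reductions negative)."""
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return 100.0 * (treatment_mean - control_mean) / control_mean


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p (t with n-2 df).

    Requires equal-length vectors of at least 3 points with non-zero
    variance in both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class QpcrRecord:
    """Replicate CT values for one target under control and treatment.

    ``*_ct`` hold target-gene cycles, ``*_ref_ct`` the reference gene's
    (e.g. U6 for MIRNAs, actin-2 for targets) under each condition.
    """

    target: str
    control_ct: list[float] = field(default_factory=list)
    control_ref_ct: list[float] = field(default_factory=list)
    treatment_ct: list[float] = field(default_factory=list)
    treatment_ref_ct: list[float] = field(default_factory=list)


def ddct_fold_change(record: QpcrRecord) -> dict:
    """Relative expression by 2^-ddCT.

    CT replicates are averaged per cell before computing
    dCT = mean(CT_target) - mean(CT_reference) per condition and
    ddCT = dCT_treatment - dCT_control.  Control expression is 1.0 by
    construction; the treatment fold change is 2^-ddCT.
    """
    for label, values in (
        ("control_ct", record.control_ct),
        ("control_ref_ct", record.control_ref_ct),
        ("treatment_ct", record.treatment_ct),
        ("treatment_ref_ct", record.treatment_ref_ct),
    ):
        if not values:
            raise ValueError(f"missing CT replicates: {label}")
    dct_control = float(np.mean(record.control_ct) - np.mean(record.control_ref_ct))
    dct_treatment = float(np.mean(record.treatment_ct) - np.mean(record.treatment_ref_ct))
    ddct = dct_treatment - dct_control
    return {
        "target": record.target,
        "delta_ct_control": dct_control,
        "delta_ct_treatment": dct_treatment,
        "delta_delta_ct": ddct,
        "control_fold": 1.0,
        "treatment_fold": float(2.0 ** (-ddct)),
    }
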
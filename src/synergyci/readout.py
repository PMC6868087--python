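"""qPCR read-out conversion: cycle thresholds to fractional effect.

Relative expression is quantified by the 2^-ΔΔCT method: per record,
ΔCT = CT_target - CT_reference; against a calibrator (here, the mean of the
stimulated-control condition), ΔΔCT = ΔCT_treated - ΔCT_calibrator and the
fold change is 2^-ΔΔCT.  The dose-effect analysis consumes the percent
reduction (1 - fold) * 100 of the inflammatory transcript, whose fraction
(reduction / 100) is the fraction affected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "CtRecord",
    "relative_expression",
    "percent_reduction",
    "reductions_from_ct_table",
]


@dataclass(frozen=True)
class CtRecord:
    """Cycle thresholds of a target and the reference gene for one sample."""

    sample: str
    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise DomainError(f"CT values must be finite for sample {self.sample!r}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_expression(treated: CtRecord, calibrator: CtRecord) -> float:
    """Fold change of the treated sample relative to the calibrator (2^-ΔΔCT)."""
    ddct = treated.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def percent_reduction(fold: float) -> float:
    """Percent reduction relative to the calibrator: (1 - fold) * 100.

    Negative values (an expression increase) are returned as-is; the
    median-effect fitting layer decides whether to keep them.
    """
    if not fold > 0:
        raise DomainError(f"fold change must be positive, got {fold!r}")
    return (1.0 - fold) * 100.0


def reductions_from_ct_table(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
    target_gene: str | None = None,
    replicate_average: Literal["fold", "ct"] = "fold",
) -> pd.DataFrame:
    """Fold changes and percent reductions from a long-format CT table.

    ``table`` has columns sample, condition, gene, ct, with one reference
    gene shared by every sample.  The calibrator ΔCT is the mean ΔCT of the
    ``calibrator_condition`` samples.  Per-sample fold changes are computed
    individually; per-condition summaries average on the fold scale by
    default (``replicate_average="ct"`` averages ΔΔCT instead, i.e. a
    geometric fold mean).

    Returns a per-sample frame with columns sample, condition, delta_ct,
    fold, pct_reduction.
    """
    required = {"sample", "condition", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"CT table lacks columns: {sorted(missing)}")
    wide = table.pivot_table(index=["sample", "condition"], columns="gene", values="ct")
    if reference_gene not in wide.columns:
        raise ConfigurationError(f"reference gene {reference_gene!r} absent from table")
    targets = [g for g in wide.columns if g != reference_gene]
    if target_gene is None:
        if len(targets) != 1:
            raise ConfigurationError(
                f"target gene ambiguous ({targets}); pass target_gene explicitly"
            )
        target_gene = targets[0]
    elif target_gene not in wide.columns:
        raise ConfigurationError(f"target gene {target_gene!r} absent from table")

    out = wide.reset_index()
    out["delta_ct"] = out[target_gene] - out[reference_gene]
    cal = out.loc[out["condition"] == calibrator_condition, "delta_ct"]
    if cal.empty:
        raise ConfigurationError(
            f"no samples with calibrator condition {calibrator_condition!r}"
        )
    cal_dct = float(cal.mean())
    out["fold"] = 2.0 ** (-(out["delta_ct"] - cal_dct))
    out["pct_reduction"] = (1.0 - out["fold"]) * 100.0
    cols = ["sample", "condition", "delta_ct", "fold", "pct_reduction"]
    result = out[cols].copy()
    result.attrs["calibrator_delta_ct"] = cal_dct
    result.attrs["replicate_average"] = replicate_average
    return result


def condition_means(per_sample: pd.DataFrame, replicate_average: Literal["fold", "ct"] = "fold") -> pd.DataFrame:
    """Per-condition mean fold and percent reduction.

    "fold" averages fold changes arithmetically; "ct" averages ΔΔCT (a
    geometric mean on the fold scale).
    """
    if replicate_average == "fold":
        fold = per_sample.groupby("condition", sort=False)["fold"].mean()
    elif replicate_average == "ct":
        logf = np.log2(per_sample["fold"])
        fold = 2.0 ** logf.groupby(per_sample["condition"], sort=False).mean()
    else:
        raise ConfigurationError(f"unknown replicate_average {replicate_average!r}")
    out = fold.reset_index()
    out["pct_reduction"] = (1.0 - out["fold"]) * 100.0
    return out
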
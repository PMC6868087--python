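"""Chou-Talalay combination-index analysis for constant-ratio designs.

For two agents combined at a fixed molar ratio, the mixture has a single
dose coordinate — the *total* molar concentration — and its own median-effect
fit.  At any fraction affected fa the combination index is the two-term
(mutually exclusive) form

    CI(fa) = (D)1 / (Dx)1  +  (D)2 / (Dx)2

where (D)1, (D)2 are the component doses of the mixture producing fa (the
ratio split of the mixture's total dose at fa) and (Dx)1, (Dx)2 the
single-agent doses producing the same fa alone.  CI < 1 indicates synergism,
CI = 1 additivity (the Loewe null), CI > 1 antagonism.  The companion
dose-reduction index DRI_i = (Dx)_i / (D)_i satisfies 1/DRI1 + 1/DRI2 = CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, DomainError
from .median_effect import MedianEffectFit, dose_at_effect

__all__ = [
    "ConstantRatioDesign",
    "CIPoint",
    "CIProfile",
    "DRIPoint",
    "DEFAULT_FA_GRID",
    "split_total_dose",
    "combination_index_at_fa",
    "ci_profile",
    "classify_interaction",
    "dose_reduction_index",
]

#: fa grid used by the classical tabulation: 0.05, 0.10, 0.20, ..., 0.90, 0.95
DEFAULT_FA_GRID: tuple[float, ...] = (
    0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95,
)

Scheme = Literal["strict", "banded"]

# Band edges and labels of the finer descriptive scale (Chou's refined
# symbols), selected with scheme="banded".
_BANDS: tuple[tuple[float, str], ...] = (
    (0.10, "very strong synergism"),
    (0.30, "strong synergism"),
    (0.70, "synergism"),
    (0.85, "moderate synergism"),
    (0.90, "slight synergism"),
    (1.10, "nearly additive"),
    (1.20, "slight antagonism"),
    (1.45, "moderate antagonism"),
    (3.30, "antagonism"),
    (10.0, "strong antagonism"),
)


@dataclass(frozen=True)
class ConstantRatioDesign:
    """Two single-agent fits, the fixed-ratio mixture fit, and the molar ratio.

    ``ratio`` is (parts of agent 1 : parts of agent 2), molar.  The mixture's
    dose coordinate is the total molar concentration of both agents; its
    components are recovered by splitting the total by the ratio.  All three
    fits must be in the same dose unit.
    """

    fit1: MedianEffectFit
    fit2: MedianEffectFit
    fit12: MedianEffectFit
    ratio: tuple[float, float]
    agent1: str = "agent1"
    agent2: str = "agent2"

    def __post_init__(self) -> None:
        p1, p2 = self.ratio
        if not (p1 > 0 and p2 > 0):
            raise DesignError(f"ratio parts must be positive, got {self.ratio!r}")
        for label, fit in (("fit1", self.fit1), ("fit2", self.fit2), ("fit12", self.fit12)):
            if not (np.isfinite(fit.dm) and fit.dm > 0):
                raise DesignError(f"{label} has non-positive dm ({fit.dm!r})")


@dataclass(frozen=True)
class CIPoint:
    """Combination index and its dose decomposition at one fraction affected."""

    fa: float
    ci: float
    d_total: float
    d1: float
    d2: float
    dx1: float
    dx2: float


@dataclass(frozen=True)
class DRIPoint:
    """Dose-reduction indices at one fraction affected."""

    fa: float
    dri1: float
    dri2: float


@dataclass(frozen=True)
class CIProfile:
    """CI values with interaction diagnoses over a fraction-affected grid."""

    design: ConstantRatioDesign
    points: tuple[CIPoint, ...]
    diagnoses: tuple[str, ...]

    @property
    def fa(self) -> np.ndarray:
        return np.array([p.fa for p in self.points])

    @property
    def ci(self) -> np.ndarray:
        return np.array([p.ci for p in self.points])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fa": [p.fa for p in self.points],
                "ci": [p.ci for p in self.points],
                "d_total": [p.d_total for p in self.points],
                "d1": [p.d1 for p in self.points],
                "d2": [p.d2 for p in self.points],
                "dx1": [p.dx1 for p in self.points],
                "dx2": [p.dx2 for p in self.points],
                "diagnosis": list(self.diagnoses),
            }
        )


def split_total_dose(d_total: float, ratio: tuple[float, float]) -> tuple[float, float]:
    """Split a mixture's total dose into component doses by the molar ratio.

    d1 = d_total * p1 / (p1 + p2), d2 = d_total * p2 / (p1 + p2), so that
    d1 + d2 = d_total and d1/d2 = p1/p2.
    """
    p1, p2 = ratio
    if not (p1 > 0 and p2 > 0):
        raise DesignError(f"ratio parts must be positive, got {ratio!r}")
    if not d_total > 0:
        raise DomainError(f"d_total must be positive, got {d_total!r}")
    total_parts = p1 + p2
    return d_total * p1 / total_parts, d_total * p2 / total_parts


def combination_index_at_fa(design: ConstantRatioDesign, fa: float) -> CIPoint:
    """Two-term combination index at one fraction affected.

    The mixture's total dose producing fa is read off its median-effect fit,
    split into components by the molar ratio, and each component is compared
    with the single-agent dose producing the same fa alone.
    """
    if not 0.0 < fa < 1.0:
        raise DomainError(f"fa must lie strictly in (0, 1), got {fa!r}")
    d_total = dose_at_effect(design.fit12, fa)
    d1, d2 = split_total_dose(d_total, design.ratio)
    dx1 = dose_at_effect(design.fit1, fa)
    dx2 = dose_at_effect(design.fit2, fa)
    ci = d1 / dx1 + d2 / dx2
    return CIPoint(fa=float(fa), ci=float(ci), d_total=float(d_total),
                   d1=float(d1), d2=float(d2), dx1=float(dx1), dx2=float(dx2))


def classify_interaction(ci: float, scheme: Scheme = "strict", tol: float = 0.05) -> str:
    """Diagnose an interaction from a combination-index value.

    The default "strict" scheme applies the CI-theorem rule with a symmetric
    tolerance band around 1: synergism if ci < 1 - tol, additive if
    |ci - 1| <= tol, antagonism if ci > 1 + tol.  The "banded" scheme maps
    ci onto the finer descriptive bands conventional in combination
    screening.
    """
    if not ci > 0:
        raise DomainError(f"ci must be positive, got {ci!r}")
    if scheme == "strict":
        if ci < 1.0 - tol:
            return "synergism"
        if ci > 1.0 + tol:
            return "antagonism"
        return "additive"
    if scheme == "banded":
        for edge, label in _BANDS:
            if ci < edge:
                return label
        return "very strong antagonism"
    raise DomainError(f"unknown classification scheme {scheme!r}")


def ci_profile(
    design: ConstantRatioDesign,
    fa_grid: Sequence[float] = DEFAULT_FA_GRID,
    scheme: Scheme = "strict",
    tol: float = 0.05,
) -> CIProfile:
    """Combination-index profile over a strictly increasing fa grid."""
    grid = tuple(float(f) for f in fa_grid)
    if len(grid) == 0:
        raise DomainError("fa_grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise DomainError("fa_grid must be strictly increasing")
    points = tuple(combination_index_at_fa(design, fa) for fa in grid)
    diagnoses = tuple(classify_interaction(p.ci, scheme=scheme, tol=tol) for p in points)
    return CIProfile(design=design, points=points, diagnoses=diagnoses)


def dose_reduction_index(design: ConstantRatioDesign, fa: float) -> DRIPoint:
    """Dose-reduction indices DRI_i = (Dx)_i / (D)_i at one fraction affected.

    DRI_i is the fold by which agent i's dose may be reduced at effect level
    fa thanks to the combination; the identity 1/DRI1 + 1/DRI2 = CI holds
    exactly.
    """
    pt = combination_index_at_fa(design, fa)
    return DRIPoint(fa=pt.fa, dri1=pt.dx1 / pt.d1, dri2=pt.dx2 / pt.d2)


def dri_profile(design: ConstantRatioDesign, fa_grid: Sequence[float] = DEFAULT_FA_GRID) -> pd.DataFrame:
    """Dose-reduction indices tabulated over a fa grid."""
    rows = [dose_reduction_index(design, fa) for fa in fa_grid]
    return pd.DataFrame(
        {"fa": [r.fa for r in rows], "dri1": [r.dri1 for r in rows], "dri2": [r.dri2 for r in rows]}
    )
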
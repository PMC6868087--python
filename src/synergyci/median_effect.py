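"""Median-effect dose-effect modelling.

The mass-action median-effect equation relates the fraction of a read-out
affected by a dose ``D`` to two parameters::

    fa / fu = (D / Dm)**m,        fu = 1 - fa

``Dm`` is the median-effect dose (the dose producing fa = 0.5, operationally
the IC50) and ``m`` is a Hill-type coefficient describing the sigmoidicity of
the dose-effect curve.  Taking logarithms gives a straight line,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

the *median-effect plot*, so (Dm, m) are estimated by ordinary least squares
on the linearised coordinates.  This module houses the equation, its
linearised fit, a four-parameter logistic cross-check, and dose/unit
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigurationError, DomainError, FittingError

__all__ = [
    "CompoundInfo",
    "DoseEffectPoint",
    "DoseEffectSeries",
    "MedianEffectFit",
    "FourParamLogisticFit",
    "linearize_series",
    "fit_median_effect",
    "effect_at_dose",
    "dose_at_effect",
    "fit_four_param_logistic",
    "mass_to_molar",
]

ClipPolicy = Literal["drop", "clip"]


@dataclass(frozen=True)
class CompoundInfo:
    """A named compound with the molar mass used for unit conversion.

    For mixtures (e.g. a fixed-composition flavonoid blend) the effective
    molar mass must be supplied explicitly by the user; it is never guessed.
    """

    name: str
    molar_mass: float  # g/mol
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ConfigurationError(
                f"molar_mass must be positive, got {self.molar_mass!r} for {self.name!r}"
            )


@dataclass(frozen=True)
class DoseEffectPoint:
    """One (dose, fraction affected) observation.

    ``effect_fa`` is the fraction affected: here, the fractional reduction of
    the read-out relative to the stimulated control (larger = more
    inhibition), constrained to [0, 1].
    """

    dose: float
    effect_fa: float
    replicate: int | str | None = None

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise DomainError(f"dose must be positive, got {self.dose!r}")
        if not 0.0 <= self.effect_fa <= 1.0:
            raise DomainError(
                f"effect_fa must lie in [0, 1], got {self.effect_fa!r}"
            )


@dataclass(frozen=True)
class DoseEffectSeries:
    """An ordered dose-effect series for one agent or one fixed-ratio mixture.

    All points share a single dose unit.  At least two distinct doses are
    required before the series can be fitted.
    """

    agent: str
    unit: str
    points: tuple[DoseEffectPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose for p in self.points], dtype=float)

    @property
    def effects(self) -> np.ndarray:
        return np.array([p.effect_fa for p in self.points], dtype=float)

    @property
    def n_distinct_doses(self) -> int:
        return len({p.dose for p in self.points})

    @classmethod
    def from_arrays(
        cls,
        agent: str,
        doses: Sequence[float],
        effects: Sequence[float],
        unit: str = "uM",
        replicates: Sequence[int | str] | None = None,
    ) -> "DoseEffectSeries":
        if len(doses) != len(effects):
            raise DomainError("doses and effects must have equal length")
        reps: Sequence[int | str | None]
        reps = replicates if replicates is not None else [None] * len(doses)
        pts = tuple(
            DoseEffectPoint(float(d), float(e), r)
            for d, e, r in zip(doses, effects, reps)
        )
        return cls(agent=agent, unit=unit, points=pts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent": self.agent,
                "dose": self.doses,
                "unit": self.unit,
                "effect": self.effects,
                "replicate": [p.replicate for p in self.points],
            }
        )


@dataclass(frozen=True)
class MedianEffectFit:
    """Estimated median-effect parameters for one series.

    ``dm`` is in the dose unit of the series that produced it; ``m`` is
    dimensionless.  ``r2`` and ``n_used`` are diagnostics of the linearised
    OLS fit.  A non-positive fitted slope is reported through ``warnings``
    rather than rejected, so degenerate inputs stay inspectable.
    """

    dm: float
    m: float
    r2: float = math.nan
    n_used: int = 0
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if math.isfinite(self.dm) and not self.dm > 0:
            raise DomainError(f"dm must be positive, got {self.dm!r}")

    def effect_at(self, dose: float | np.ndarray) -> float | np.ndarray:
        return effect_at_dose(self, dose)

    def dose_at(self, fa: float | np.ndarray) -> float | np.ndarray:
        return dose_at_effect(self, fa)


@dataclass(frozen=True)
class FourParamLogisticFit:
    """Four-parameter logistic (sigmoidal IC50) fit.

    Model: effect = bottom + (top - bottom) / (1 + (ic50 / dose)**hill).
    With bottom = 0 and top = 1 the parameterisation coincides with the
    median-effect equation, so (ic50, hill) ≡ (dm, m) on exact data.
    """

    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    constrained: bool = False

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise DomainError(f"ic50 must be positive, got {self.ic50!r}")

    def predict(self, dose: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(dose, dtype=float)
        out = self.bottom + (self.top - self.bottom) / (1.0 + (self.ic50 / d) ** self.hill)
        return out if out.ndim else float(out)


def _usable_effects(
    doses: np.ndarray,
    effects: np.ndarray,
    clip_eps: float,
    policy: ClipPolicy,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the boundary policy to fa values at or outside (0, 1)."""
    if not 0.0 < clip_eps < 0.5:
        raise DomainError(f"clip_eps must lie in (0, 0.5), got {clip_eps!r}")
    if policy == "drop":
        keep = (effects > 0.0) & (effects < 1.0)
        return doses[keep], effects[keep]
    if policy == "clip":
        return doses, np.clip(effects, clip_eps, 1.0 - clip_eps)
    raise ConfigurationError(f"unknown boundary policy {policy!r}")


def linearize_series(
    series: DoseEffectSeries,
    clip_eps: float = 1e-3,
    policy: ClipPolicy = "drop",
) -> np.ndarray:
    """Median-effect-plot coordinates (log10 D, log10(fa/fu)) for a series.

    Points with fa exactly 0 or 1 have no finite linearised coordinate and
    are dropped or clipped to [clip_eps, 1 - clip_eps] according to
    ``policy``.  Input order is preserved.

    Returns an (n, 2) array of (x, y) pairs.

    Raises
    ------
    FittingError
        If fewer than two usable points remain.
    """
    doses, effects = _usable_effects(series.doses, series.effects, clip_eps, policy)
    if len(doses) < 2:
        raise FittingError(
            f"series {series.agent!r}: fewer than 2 usable points after "
            f"{policy!r} policy (got {len(doses)})"
        )
    x = np.log10(doses)
    y = np.log10(effects / (1.0 - effects))
    return np.column_stack([x, y])


def fit_median_effect(
    series: DoseEffectSeries,
    clip_eps: float = 1e-3,
    policy: ClipPolicy = "drop",
    average_replicates: bool = False,
) -> MedianEffectFit:
    """Fit (Dm, m) by unweighted OLS on the median-effect plot.

    The slope of the linearised fit is ``m`` and the intercept is
    ``-m * log10(Dm)``, so ``Dm = 10**(-intercept / m)``.  By default every
    individual point enters the regression (pooled OLS); with
    ``average_replicates`` effects are first averaged per distinct dose.

    Raises
    ------
    FittingError
        If fewer than two usable points remain, or all usable doses coincide.
    """
    if average_replicates:
        df = pd.DataFrame({"dose": series.doses, "fa": series.effects})
        grouped = df.groupby("dose", sort=False)["fa"].mean().reset_index()
        series = DoseEffectSeries.from_arrays(
            series.agent, grouped["dose"], grouped["fa"], unit=series.unit
        )
    pairs = linearize_series(series, clip_eps=clip_eps, policy=policy)
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0.0:
        raise FittingError(
            f"series {series.agent!r}: all usable doses identical; slope undefined"
        )
    res = stats.linregress(x, y)
    m = float(res.slope)
    warnings: tuple[str, ...] = ()
    if m <= 0:
        warnings = (f"non-positive fitted slope m={m:.6g}; dm unreliable",)
        dm = math.nan if m == 0 else float(10.0 ** (-res.intercept / m))
        if dm is not math.nan and not dm > 0:
            dm = math.nan
    else:
        dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(
        dm=dm, m=m, r2=float(res.rvalue**2), n_used=len(x), warnings=warnings
    )


def effect_at_dose(fit: MedianEffectFit, dose: float | np.ndarray) -> float | np.ndarray:
    """Fraction affected at a dose: fa = 1 / (1 + (dm/dose)**m).

    Strictly increasing in dose for m > 0.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise DomainError(f"dose must be positive, got {dose!r}")
    fa = 1.0 / (1.0 + (fit.dm / d) ** fit.m)
    return fa if fa.ndim else float(fa)


def dose_at_effect(fit: MedianEffectFit, fa: float | np.ndarray) -> float | np.ndarray:
    """Dose producing a fraction affected: D = dm * (fa/(1-fa))**(1/m).

    The boundary effects fa = 0 and fa = 1 require zero or infinite dose and
    are rejected.
    """
    if fit.m == 0:
        raise DomainError("dose_at_effect undefined for m == 0")
    f = np.asarray(fa, dtype=float)
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise DomainError(f"fa must lie strictly in (0, 1), got {fa!r}")
    d = fit.dm * (f / (1.0 - f)) ** (1.0 / fit.m)
    return d if d.ndim else float(d)


def _fpl(d, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (ic50 / d) ** hill)


def fit_four_param_logistic(
    series: DoseEffectSeries,
    constrained: bool | None = None,
    maxfev: int = 10000,
) -> FourParamLogisticFit:
    """Nonlinear least-squares fit of the four-parameter logistic curve.

    Serves as a cross-check on the linearised median-effect fit: with the
    asymptotes constrained to bottom = 0, top = 1 the two parameterisations
    are identical, so (ic50, hill) must match (dm, m) on exact data.

    With fewer than four distinct doses the free four-parameter problem is
    under-determined and the constrained fit is used regardless of
    ``constrained``.
    """
    d, fa = series.doses, series.effects
    if constrained is None:
        constrained = series.n_distinct_doses < 4
    elif not constrained and series.n_distinct_doses < 4:
        constrained = True
    ic50_guess = float(np.exp(np.mean(np.log(d))))
    try:
        if constrained:
            popt, _ = optimize.curve_fit(
                lambda x, ic50, hill: _fpl(x, 0.0, 1.0, ic50, hill),
                d,
                fa,
                p0=[ic50_guess, 1.0],
                bounds=([1e-12, -50.0], [np.inf, 50.0]),
                maxfev=maxfev,
            )
            bottom, top = 0.0, 1.0
            ic50, hill = map(float, popt)
        else:
            popt, _ = optimize.curve_fit(
                _fpl,
                d,
                fa,
                p0=[float(fa.min()), float(fa.max()), ic50_guess, 1.0],
                bounds=([-1.0, -1.0, 1e-12, -50.0], [2.0, 2.0, np.inf, 50.0]),
                maxfev=maxfev,
            )
            bottom, top, ic50, hill = map(float, popt)
    except RuntimeError as exc:  # curve_fit non-convergence
        raise FittingError(
            f"four-parameter logistic fit failed for {series.agent!r}: {exc}"
        ) from exc
    rss = float(np.sum((_fpl(d, bottom, top, ic50, hill) - fa) ** 2))
    return FourParamLogisticFit(
        bottom=bottom, top=top, ic50=ic50, hill=hill, rss=rss, constrained=constrained
    )


def mass_to_molar(conc_ug_per_ml: float | np.ndarray, compound: CompoundInfo) -> float | np.ndarray:
    """Convert a mass concentration (µg/ml) to a molar one (µM).

    µM = µg/ml / (g/mol) * 1000.
    """
    c = np.asarray(conc_ug_per_ml, dtype=float)
    if np.any(c < 0):
        raise DomainError(f"concentration must be non-negative, got {conc_ug_per_ml!r}")
    out = c / compound.molar_mass * 1000.0
    return out if out.ndim else float(out)


def series_mass_to_molar(series: DoseEffectSeries, compound: CompoundInfo) -> DoseEffectSeries:
    """Rescale every dose of a µg/ml series to µM using a compound's molar mass."""
    return DoseEffectSeries.from_arrays(
        series.agent,
        mass_to_molar(series.doses, compound),
        series.effects,
        unit="uM",
        replicates=[p.replicate for p in series.points],
    )
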
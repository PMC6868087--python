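"""Synthetic dose-effect and CT data with known ground truth.

The generator forward-simulates the median-effect law for two single agents
and a constant-ratio mixture, so every stage of the analysis can be tested
for parameter and interaction recovery without external data.  The mixture
backbone is built from the Loewe-additivity null — the total dose at which
the ratio-split components exactly exhaust their single-agent isoboles — and
an interaction multiplier ``kappa`` shifts its potency uniformly: kappa = 1
gives CI = 1 everywhere (additivity); kappa = 0.5 halves the mixture dose
needed for every effect (CI = 0.5, synergism) when the slopes are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, DomainError
from .median_effect import DoseEffectSeries, MedianEffectFit, dose_at_effect, effect_at_dose

__all__ = [
    "SimulationSpec",
    "CtSimParams",
    "simulate_single_agent",
    "additive_mixture_fit",
    "loewe_additive_total_dose",
    "simulate_combination",
    "simulate_ct_table",
    "simulate_ct_dataset",
]

NoiseModel = Literal["none", "additive-fa", "multiplicative-fold"]

# RNG stream ids: keep single-agent, mixture, and CT draws independent but
# jointly deterministic under one seed.
_STREAM_AGENT1, _STREAM_AGENT2, _STREAM_MIXTURE, _STREAM_CT = 1, 2, 3, 4


def _as_fit(fit: MedianEffectFit | tuple[float, float]) -> MedianEffectFit:
    if isinstance(fit, MedianEffectFit):
        return fit
    dm, m = fit
    return MedianEffectFit(dm=float(dm), m=float(m))


def _default_grid(dm: float) -> tuple[float, ...]:
    """Five-dose two-fold ladder spanning dm/4 .. 4*dm."""
    return tuple(dm * f for f in (0.25, 0.5, 1.0, 2.0, 4.0))


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth, design, noise model, and seed for one simulated study.

    ``interaction_kappa`` multiplies the Loewe-additive mixture potency
    curve: the mixture dose producing each effect is kappa times the
    additive dose, so kappa equals the (flat) combination index when the
    slopes agree.  ``true_mixture`` overrides the constructed backbone with
    an explicit (dm, m), which is how effect-dependent interaction profiles
    (CI varying with fa) are produced.
    """

    true_fit1: tuple[float, float] = (14.28, 1.835)
    true_fit2: tuple[float, float] = (91.2, 2.005)
    ratio: tuple[float, float] = (1.0, 7.3)
    interaction_kappa: float = 1.0
    true_mixture: tuple[float, float] | None = None
    dose_grid1: tuple[float, ...] | None = None
    dose_grid2: tuple[float, ...] | None = None
    dose_grid12: tuple[float, ...] | None = None
    noise_model: NoiseModel = "additive-fa"
    noise_scale: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    agent1: str = "agent1"
    agent2: str = "agent2"
    unit: str = "uM"

    def __post_init__(self) -> None:
        if not self.interaction_kappa > 0:
            raise DesignError(f"interaction_kappa must be positive, got {self.interaction_kappa!r}")
        if self.noise_scale < 0:
            raise DesignError(f"noise_scale must be non-negative, got {self.noise_scale!r}")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        for grid in (self.dose_grid1, self.dose_grid2, self.dose_grid12):
            if grid is not None:
                g = np.asarray(grid, dtype=float)
                if g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
                    raise DesignError(f"dose grid must be positive and sorted, got {grid!r}")

    @property
    def mixture_label(self) -> str:
        return f"{self.agent1}+{self.agent2}"

    def grid_for(self, which: int) -> tuple[float, ...]:
        if which == 1:
            return self.dose_grid1 or _default_grid(_as_fit(self.true_fit1).dm)
        if which == 2:
            return self.dose_grid2 or _default_grid(_as_fit(self.true_fit2).dm)
        raise DomainError(f"which_agent must be 1 or 2, got {which!r}")

    def mixture_backbone(self) -> MedianEffectFit:
        """Closed-form mixture fit (requires equal slopes unless overridden)."""
        if self.true_mixture is not None:
            return _as_fit(self.true_mixture)
        base = additive_mixture_fit(_as_fit(self.true_fit1), _as_fit(self.true_fit2), self.ratio)
        return replace(base, dm=base.dm * self.interaction_kappa)

    def mixture_grid(self) -> tuple[float, ...]:
        if self.dose_grid12 is not None:
            return self.dose_grid12
        f1, f2 = _as_fit(self.true_fit1), _as_fit(self.true_fit2)
        if self.true_mixture is not None or np.isclose(f1.m, f2.m, rtol=1e-9, atol=0.0):
            return _default_grid(self.mixture_backbone().dm)
        dm_numeric = self.interaction_kappa * loewe_additive_total_dose(f1, f2, self.ratio, 0.5)
        return _default_grid(dm_numeric)


def _apply_noise(
    fa: np.ndarray, model: NoiseModel, scale: float, rng: np.random.Generator
) -> np.ndarray:
    if scale == 0.0 or model == "none":
        return fa.copy()
    if model == "additive-fa":
        return np.clip(fa + rng.normal(0.0, scale, size=fa.shape), 0.0, 1.0)
    if model == "multiplicative-fold":
        # lognormal jitter on the unaffected fraction (the fold change)
        fu = (1.0 - fa) * np.exp(rng.normal(0.0, scale, size=fa.shape))
        return np.clip(1.0 - fu, 0.0, 1.0)
    raise DesignError(f"unknown noise model {model!r}")


def _make_series(
    agent: str,
    unit: str,
    grid: Sequence[float],
    backbone_fa: np.ndarray,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> DoseEffectSeries:
    doses, effects, reps = [], [], []
    for rep in range(1, spec.n_replicates + 1):
        noisy = _apply_noise(backbone_fa, spec.noise_model, spec.noise_scale, rng)
        doses.extend(grid)
        effects.extend(noisy)
        reps.extend([rep] * len(grid))
    return DoseEffectSeries.from_arrays(agent, doses, effects, unit=unit, replicates=reps)


def simulate_single_agent(spec: SimulationSpec, which_agent: int = 1) -> DoseEffectSeries:
    """Simulate one agent's dose-effect series from its true (dm, m).

    Noise-free points lie exactly on the median-effect curve; replicate noise
    follows the configured model, with effects clamped to [0, 1].
    Deterministic given the configured seed.
    """
    fit = _as_fit(spec.true_fit1 if which_agent == 1 else spec.true_fit2)
    grid = spec.grid_for(which_agent)
    agent = spec.agent1 if which_agent == 1 else spec.agent2
    stream = _STREAM_AGENT1 if which_agent == 1 else _STREAM_AGENT2
    rng = np.random.default_rng([spec.seed, stream])
    backbone = np.asarray(effect_at_dose(fit, np.asarray(grid)))
    return _make_series(agent, spec.unit, grid, backbone, spec, rng)


def additive_mixture_fit(
    fit1: MedianEffectFit | tuple[float, float],
    fit2: MedianEffectFit | tuple[float, float],
    ratio: tuple[float, float],
) -> MedianEffectFit:
    """Median-effect fit of the exactly Loewe-additive fixed-ratio mixture.

    When both agents share a slope m, the additive mixture is itself a
    median-effect curve with the same slope and total-dose median

        dm_add = (p1 + p2) / (p1/dm1 + p2/dm2)

    (the ratio-weighted harmonic combination of the component medians), and
    the CI computed against it is 1 at every fa.  With unequal slopes no
    median-effect-form additive mixture exists; use
    :func:`loewe_additive_total_dose` for the effect-by-effect curve.
    """
    f1, f2 = _as_fit(fit1), _as_fit(fit2)
    p1, p2 = ratio
    if not (p1 > 0 and p2 > 0):
        raise DesignError(f"ratio parts must be positive, got {ratio!r}")
    if not np.isclose(f1.m, f2.m, rtol=1e-9, atol=0.0):
        raise DesignError(
            f"closed-form additive mixture requires equal slopes (m1={f1.m}, m2={f2.m}); "
            "use loewe_additive_total_dose for the numeric effect-by-effect curve"
        )
    dm_add = (p1 + p2) / (p1 / f1.dm + p2 / f2.dm)
    return MedianEffectFit(dm=float(dm_add), m=float(f1.m), r2=1.0)


def loewe_additive_total_dose(
    fit1: MedianEffectFit | tuple[float, float],
    fit2: MedianEffectFit | tuple[float, float],
    ratio: tuple[float, float],
    fa: float | np.ndarray,
) -> float | np.ndarray:
    """Total mixture dose at which the ratio-split components are Loewe-additive.

    Solving d1/Dx1(fa) + d2/Dx2(fa) = 1 with d_i the ratio fractions of the
    total gives D_add(fa) = (p1+p2) / (p1/Dx1 + p2/Dx2) — valid for any pair
    of slopes.
    """
    f1, f2 = _as_fit(fit1), _as_fit(fit2)
    p1, p2 = ratio
    dx1 = dose_at_effect(f1, fa)
    dx2 = dose_at_effect(f2, fa)
    return (p1 + p2) / (p1 / np.asarray(dx1) + p2 / np.asarray(dx2))


def simulate_combination(spec: SimulationSpec) -> DoseEffectSeries:
    """Simulate the fixed-ratio mixture series; dose = total molar concentration.

    The backbone is the Loewe-additive curve scaled by ``kappa`` (or the
    explicit ``true_mixture`` fit).  With equal single-agent slopes the
    backbone is evaluated in closed form; otherwise the effect at each total
    dose is found by root-finding on the monotone additive dose curve.
    """
    grid = np.asarray(spec.mixture_grid(), dtype=float)
    f1, f2 = _as_fit(spec.true_fit1), _as_fit(spec.true_fit2)
    if spec.true_mixture is not None or np.isclose(f1.m, f2.m, rtol=1e-9, atol=0.0):
        backbone = np.asarray(effect_at_dose(spec.mixture_backbone(), grid))
    else:
        from scipy.optimize import brentq

        def fa_at(d: float) -> float:
            lo, hi = 1e-12, 1.0 - 1e-12
            g = lambda fa: spec.interaction_kappa * float(
                loewe_additive_total_dose(f1, f2, spec.ratio, fa)
            ) - d
            return brentq(g, lo, hi, xtol=1e-14, rtol=1e-14)

        backbone = np.array([fa_at(float(d)) for d in grid])
    rng = np.random.default_rng([spec.seed, _STREAM_MIXTURE])
    return _make_series(spec.mixture_label, spec.unit, grid, backbone, spec, rng)


@dataclass(frozen=True)
class CtSimParams:
    """Instrument-level parameters for synthetic CT tables."""

    target_gene: str = "IL1B"
    reference_gene: str = "ACTB"
    ct_reference: float = 16.0   # reference-gene CT baseline
    dct_calibrator: float = 5.0  # target-minus-reference CT in the calibrator
    ct_noise_sd: float = 0.0     # extra Gaussian noise per CT measurement


def simulate_ct_table(
    target_reductions: Mapping[str, float],
    params: CtSimParams = CtSimParams(),
    n_replicates: int = 1,
    seed: int = 0,
    calibrator_condition: str = "control",
) -> pd.DataFrame:
    """CT records that reproduce given percent reductions through 2^-ΔΔCT.

    ``target_reductions`` maps condition labels to percent reductions
    (< 100; 100% would need a non-positive fold).  The calibrator condition
    is emitted with ΔΔCT = 0.  Passing the table through the read-out module
    recovers the targets exactly when ``ct_noise_sd`` is zero.
    """
    for cond, red in target_reductions.items():
        if red >= 100.0:
            raise DomainError(
                f"target reduction must be < 100% (fold > 0); got {red!r} for {cond!r}"
            )
    rng = np.random.default_rng([seed, _STREAM_CT])
    rows: list[dict] = []
    conditions = [(calibrator_condition, 0.0)] + list(target_reductions.items())
    for cond, red in conditions:
        ddct = -np.log2(1.0 - red / 100.0)
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            ct_ref = params.ct_reference
            ct_tgt = params.ct_reference + params.dct_calibrator + ddct
            if params.ct_noise_sd > 0:
                ct_ref += rng.normal(0.0, params.ct_noise_sd)
                ct_tgt += rng.normal(0.0, params.ct_noise_sd)
            rows.append({"sample": sample, "condition": cond,
                         "gene": params.reference_gene, "ct": ct_ref})
            rows.append({"sample": sample, "condition": cond,
                         "gene": params.target_gene, "ct": ct_tgt})
    return pd.DataFrame(rows)


def simulate_ct_dataset(
    spec: SimulationSpec,
    params: CtSimParams = CtSimParams(),
    calibrator_condition: str = "stimulated",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full synthetic qPCR experiment for a two-agent constant-ratio study.

    Simulates the three dose-effect series (both agents and the mixture),
    converts each noisy fractional effect into a per-sample CT pair, and
    returns (ct_table, design_table) where ``design_table`` maps each
    condition label back to its (agent, dose, replicate).  Feeding the CT
    table through the read-out module and refitting recovers the planted
    interaction.
    """
    series = [
        simulate_single_agent(spec, 1),
        simulate_single_agent(spec, 2),
        simulate_combination(spec),
    ]
    rng = np.random.default_rng([spec.seed, _STREAM_CT])
    ct_rows: list[dict] = []
    design_rows: list[dict] = []

    def emit(sample: str, condition: str, fa: float) -> None:
        # fa = 1 - fold  =>  ddct = -log2(1 - fa); fa is clamped below 1.
        fa = min(fa, 1.0 - 1e-9)
        ddct = -np.log2(1.0 - fa)
        ct_ref = params.ct_reference
        ct_tgt = params.ct_reference + params.dct_calibrator + ddct
        if params.ct_noise_sd > 0:
            ct_ref += rng.normal(0.0, params.ct_noise_sd)
            ct_tgt += rng.normal(0.0, params.ct_noise_sd)
        ct_rows.append({"sample": sample, "condition": condition,
                        "gene": params.reference_gene, "ct": ct_ref})
        ct_rows.append({"sample": sample, "condition": condition,
                        "gene": params.target_gene, "ct": ct_tgt})

    for rep in range(1, spec.n_replicates + 1):
        emit(f"{calibrator_condition}_r{rep}", calibrator_condition, 0.0)
    for s in series:
        for i, pt in enumerate(s.points):
            cond = f"{s.agent}@{pt.dose:.6g}"
            sample = f"{cond}_r{pt.replicate}"
            emit(sample, cond, pt.effect_fa)
            design_rows.append({"condition": cond, "agent": s.agent,
                                "dose": pt.dose, "replicate": pt.replicate,
                                "unit": s.unit})
    return pd.DataFrame(ct_rows), pd.DataFrame(design_rows)
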
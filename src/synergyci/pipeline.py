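"""End-to-end analysis pipeline: CSV in, fit/CI/DRI report bundle out.

One YAML configuration drives the whole analysis: read a long-format
dose-effect table, fit the median-effect parameters of both single agents
and the fixed-ratio mixture, compute the combination-index and
dose-reduction-index profiles, and write a deterministic report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combination import (
    DEFAULT_FA_GRID,
    CIProfile,
    ConstantRatioDesign,
    ci_profile,
    dri_profile,
)
from .exceptions import ConfigurationError
from .median_effect import (
    CompoundInfo,
    DoseEffectSeries,
    MedianEffectFit,
    fit_median_effect,
    linearize_series,
    series_mass_to_molar,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "write_report",
           "read_dose_effect_csv"]

log = logging.getLogger("synergyci")

_MASS_UNITS = {"ug/ml", "µg/ml", "ug_ml"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to run one two-agent constant-ratio analysis."""

    data: str                      # long-format dose-effect CSV
    agent1: str
    agent2: str
    mixture: str
    ratio: tuple[float, float]
    output_dir: str = "synergyci_out"
    compounds: Mapping[str, float] = field(default_factory=dict)  # name -> g/mol
    convert_to_molar: bool = False
    effect_percent: bool = False   # effect column is percent reduction, not a fraction
    fa_grid: tuple[float, ...] = DEFAULT_FA_GRID
    scheme: str = "strict"
    tol: float = 0.05
    clip_policy: str = "drop"
    clip_eps: float = 1e-3
    average_replicates: bool = False
    ci_decimals: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "ratio" in raw:
            raw["ratio"] = tuple(float(x) for x in raw["ratio"])
        if "fa_grid" in raw:
            raw["fa_grid"] = tuple(float(x) for x in raw["fa_grid"])
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) if not isinstance(getattr(self, k), Mapping)
             else dict(getattr(self, k)) for k in self.__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class AnalysisReport:
    """In-memory results of one full analysis run."""

    fits: Mapping[str, MedianEffectFit]
    profile: CIProfile
    dri: pd.DataFrame
    output_dir: Path


def read_dose_effect_csv(
    path: str | Path, effect_percent: bool = False
) -> dict[str, DoseEffectSeries]:
    """Parse a long-format dose-effect CSV into per-agent series.

    Expected columns: agent, dose, unit, effect (+ optional replicate).
    With ``effect_percent`` the effect column is a percent reduction and is
    divided by 100; negative reductions are floored at 0 (no effect) so the
    fitting layer's boundary policy decides their fate.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ConfigurationError(f"malformed CSV {path}: {exc}") from exc
    required = {"agent", "dose", "unit", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~np.isfinite(df["dose"]) | (df["dose"] <= 0)]
    if not bad.empty:
        raise ConfigurationError(
            f"{path}: non-positive dose at row(s) {list(bad.index[:5])}"
        )
    series: dict[str, DoseEffectSeries] = {}
    for agent, sub in df.groupby("agent", sort=False):
        units = sub["unit"].unique()
        if len(units) != 1:
            raise ConfigurationError(f"agent {agent!r} mixes dose units {list(units)}")
        effect = sub["effect"].to_numpy(dtype=float)
        if effect_percent:
            effect = effect / 100.0
        effect = np.clip(effect, 0.0, 1.0)
        reps = sub["replicate"].tolist() if "replicate" in sub.columns else None
        series[str(agent)] = DoseEffectSeries.from_arrays(
            str(agent), sub["dose"].to_numpy(dtype=float), effect,
            unit=str(units[0]), replicates=reps,
        )
    return series


def _fmt(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.{decimals}f}")
    return out


def write_report(
    profile: CIProfile,
    fits: Mapping[str, MedianEffectFit],
    destination: str | Path,
    ci_decimals: int = 4,
    dri: pd.DataFrame | None = None,
    plot_coords: pd.DataFrame | None = None,
    plot_lines: pd.DataFrame | None = None,
    header_lines: Sequence[str] = (),
) -> list[Path]:
    """Write the report bundle; identical inputs give byte-identical files.

    Emits fits.csv, ci_profile.csv, and optionally dri.csv and the
    median-effect-plot coordinate files; float columns are printed at a
    fixed number of decimals so reruns are reproducible byte for byte.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fit_rows = [
        {"agent": name, "dm": f.dm, "m": f.m, "r2": f.r2, "n_used": f.n_used}
        for name, f in fits.items()
    ]
    fits_df = pd.DataFrame(fit_rows, columns=["agent", "dm", "m", "r2", "n_used"])
    p = dest / "fits.csv"
    _fmt(fits_df, ci_decimals).to_csv(p, index=False)
    written.append(p)

    p = dest / "ci_profile.csv"
    _fmt(profile.to_dataframe(), ci_decimals).to_csv(p, index=False)
    written.append(p)

    if dri is not None:
        p = dest / "dri.csv"
        _fmt(dri, ci_decimals).to_csv(p, index=False)
        written.append(p)
    if plot_coords is not None:
        p = dest / "median_effect_points.csv"
        _fmt(plot_coords, ci_decimals).to_csv(p, index=False)
        written.append(p)
    if plot_lines is not None:
        p = dest / "median_effect_lines.csv"
        _fmt(plot_lines, ci_decimals).to_csv(p, index=False)
        written.append(p)

    summary = list(header_lines)
    summary.append("agent fits (dm, m, r2):")
    for name, f in fits.items():
        summary.append(f"  {name}: dm={f.dm:.4f} m={f.m:.4f} r2={f.r2:.4f}")
    summary.append("combination index profile:")
    for pt, diag in zip(profile.points, profile.diagnoses):
        summary.append(f"  fa={pt.fa:.2f}  CI={pt.ci:.{ci_decimals}f}  {diag}")
    p = dest / "summary.txt"
    p.write_text("\n".join(summary) + "\n")
    written.append(p)
    return written


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the whole constant-ratio combination analysis from one config.

    Fits each configured series, builds the constant-ratio design, computes
    the CI and DRI profiles over the configured fa grid, and writes the
    report bundle to ``config.output_dir``.
    """
    log.info("synergyci %s | config hash %s | seed %d",
             __version__, config.content_hash(), config.seed)
    series = read_dose_effect_csv(config.data, effect_percent=config.effect_percent)
    for label in (config.agent1, config.agent2, config.mixture):
        if label not in series:
            raise ConfigurationError(
                f"agent {label!r} not present in {config.data} "
                f"(found: {sorted(series)})"
            )
    chosen = {k: series[k] for k in (config.agent1, config.agent2, config.mixture)}

    if config.convert_to_molar:
        converted = {}
        for label, s in chosen.items():
            if s.unit.lower() in _MASS_UNITS:
                if label not in config.compounds:
                    raise ConfigurationError(
                        f"compound registry lacks a molar mass for {label!r}"
                    )
                converted[label] = series_mass_to_molar(
                    s, CompoundInfo(label, float(config.compounds[label]))
                )
            else:
                converted[label] = s
        chosen = converted

    units = {s.unit for s in chosen.values()}
    if len(units) != 1:
        raise ConfigurationError(f"series dose units differ: {sorted(units)}")

    fits: dict[str, MedianEffectFit] = {}
    coords_rows, line_rows = [], []
    for label, s in chosen.items():
        fit = fit_median_effect(
            s, clip_eps=config.clip_eps, policy=config.clip_policy,  # type: ignore[arg-type]
            average_replicates=config.average_replicates,
        )
        fits[label] = fit
        pairs = linearize_series(s, clip_eps=config.clip_eps,
                                 policy=config.clip_policy)  # type: ignore[arg-type]
        for x, y in pairs:
            coords_rows.append({"agent": label, "x": x, "y": y})
        x0, x1 = float(pairs[:, 0].min()), float(pairs[:, 0].max())
        intercept = -fit.m * np.log10(fit.dm)
        line_rows.append({"agent": label, "x0": x0, "y0": fit.m * x0 + intercept,
                          "x1": x1, "y1": fit.m * x1 + intercept})
        log.info("fit %s: dm=%.4g m=%.4g r2=%.4f n=%d%s", label, fit.dm, fit.m,
                 fit.r2, fit.n_used,
                 f" [warnings: {'; '.join(fit.warnings)}]" if fit.warnings else "")

    design = ConstantRatioDesign(
        fit1=fits[config.agent1], fit2=fits[config.agent2],
        fit12=fits[config.mixture], ratio=config.ratio,
        agent1=config.agent1, agent2=config.agent2,
    )
    profile = ci_profile(design, fa_grid=config.fa_grid,
                         scheme=config.scheme, tol=config.tol)  # type: ignore[arg-type]
    dri = dri_profile(design, fa_grid=config.fa_grid)

    header = [
        f"synergyci {__version__}",
        f"config hash: {config.content_hash()}",
        f"seed: {config.seed}",
        f"design: {config.agent1} + {config.agent2} at molar ratio "
        f"{config.ratio[0]:g}:{config.ratio[1]:g}",
    ]
    out_dir = Path(config.output_dir)
    write_report(
        profile, fits, out_dir, ci_decimals=config.ci_decimals, dri=dri,
        plot_coords=pd.DataFrame(coords_rows), plot_lines=pd.DataFrame(line_rows),
        header_lines=header,
    )
    return AnalysisReport(fits=fits, profile=profile, dri=dri, output_dir=out_dir)
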
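# Methods

## Dose–effect model

All fitting rests on the median-effect equation, `fa/fu = (D/Dm)^m` with
`fu = 1 − fa`. Its assumptions are those of a mass-action dose–effect law:
a single sigmoidal transition, effect bounded in [0, 1], and dose acting
through a single potency scale `Dm`. The effect orientation throughout the
package is *fractional reduction* of the read-out relative to the stimulated
control (percent reduction ÷ 100), so larger `fa` means stronger inhibition.

Estimation linearises the equation as
`log10(fa/fu) = m·log10 D − m·log10 Dm` and fits unweighted ordinary least
squares — the classical median-effect procedure. Any log base gives the
same (Dm, m); base 10 matches the plotting convention. Consequences of the
unweighted choice are real: points near fa = 0 or 1 carry strongly inflated
variance on the linearised scale, which is visible in the noisy-recovery
calibration below. No weighted or robust variant is fitted by default.

Boundary effects (fa ≤ 0 or ≥ 1) have no finite linearised coordinate. The
default policy **drops** them; an alternative **clips** into
[eps, 1 − eps] with eps = 1e-3 by default (configurable in (0, 0.5)). A
fit needs at least two distinct usable doses. Replicates are pooled into a
single OLS by default (each point is one observation); a flag averages
effects per dose first. A non-positive fitted slope is returned with a
warning flag rather than an exception, so degenerate inputs remain
inspectable; `dm` is then unreliable (NaN when the slope is exactly zero).

A four-parameter logistic fit,
`effect = bottom + (top − bottom)/(1 + (ic50/D)^hill)`, is provided as a
cross-check (nonlinear least squares, scipy `curve_fit`). With
`bottom = 0, top = 1` the parameterisation coincides with the median-effect
curve, so (ic50, hill) must equal (Dm, m) on exact data — a property the
test suite asserts to 1e-6. With fewer than four distinct doses the free
fit is under-determined and the constrained form is used automatically.

## Combination index

For two agents at fixed molar ratio `p1:p2`, the mixture's dose coordinate
is the total molar concentration; its components are the ratio split
`d_i = d_total·p_i/(p1+p2)`. At each fraction affected the mixture's total
dose is read off the mixture's own median-effect fit, and

`CI(fa) = d1/Dx1(fa) + d2/Dx2(fa)`

with `Dx_i` the single-agent dose for the same effect. This is the two-term
(mutually exclusive) form; the three-term non-exclusive variant is not
implemented — the two-term form is what the upstream tabulations use, and
the package reproduces them to their printed precision from the printed
(Dm, m, ratio) inputs alone (the test suite freezes both reference tables).

The dose-reduction index is `DRI_i = Dx_i/d_i`; the identity
`1/DRI1 + 1/DRI2 = CI` is exact and asserted to 1e-12 on random designs.

Classification defaults to the *strict* scheme — synergism below `1 − tol`,
additive within `±tol`, antagonism above `1 + tol`, with `tol = 0.05` — and
a *banded* scheme maps CI to the conventional finer labels (very strong
synergism < 0.1, …, nearly additive 0.90–1.10, …). The tolerance exists
because a point estimate exactly at 1 is never observed with finite data;
±0.05 is a conventional reading band, not an inferential statement. Note
that published diagnosis columns sometimes label CI values as high as ~1.5
"additive"; no defensible band reproduces that, so the numeric CI column is
the authoritative output and the diagnosis is always derived from the
declared scheme.

Default fa grid: 0.05, 0.10, 0.20, …, 0.90, 0.95 (the classical
tabulation); fully configurable.

## qPCR read-out

Relative expression uses 2^-ΔΔCT: per sample
`ΔCT = CT_target − CT_reference`; the calibrator ΔCT is the mean over the
stimulated-control samples; `fold = 2^−ΔΔCT`; percent reduction is
`(1 − fold)·100`. Per-condition summaries average on the fold scale by
default, with a ΔΔCT-scale (geometric) alternative. Negative reductions
(expression increases) are preserved in tables but excluded from
median-effect fitting by the default drop policy. Amplification-efficiency
correction and instrument-file parsing are out of scope.

## Synthetic-data generator

The generator emulates the statistical shape of the study design: per agent
a 5-dose two-fold ladder, a fixed-ratio mixture arm whose dose is the total
molar concentration, replicate noise, and optionally the qPCR layer
(CT pairs that decode to the intended reductions).

Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| true (Dm, m), agent 1 | (14.28 µM, 1.835) | curcumin-scale potency/slope |
| true (Dm, m), agent 2 | (91.2 µM, 2.005) | flavonoid-mixture-scale potency |
| molar ratio | 1:7.3 | ratio of the reference design |
| dose grids | dm·{¼, ½, 1, 2, 4} | 5-dose two-fold ladder centred on each series' own median, the design shape of the emulated experiments; explicit grids (e.g. µg/ml ladders) may be passed |
| noise model | additive Gaussian on fa, truncated to [0, 1] | simplest falsifiable choice given that source data report only mean ± SD; a multiplicative-on-fold (lognormal on fu) alternative is selectable |
| noise_scale | 0 | noise is opt-in |
| n_replicates | 1 | |

The mixture backbone is built from the Loewe-additivity null. With equal
slopes the additive mixture is itself a median-effect curve with
`dm_add = (p1+p2)/(p1/dm1 + p2/dm2)` and the same m, and the downstream CI
is 1 at every fa to 1e-9. With unequal slopes no closed-form additive
median-effect curve exists; the generator then evaluates the exact
effect-by-effect additive dose `D_add(fa) = (p1+p2)/(p1/Dx1 + p2/Dx2)` and
inverts it by root-finding (Brent, tolerance 1e-14). The interaction
multiplier `kappa` scales the mixture's potency uniformly
(`D_mix(fa) = kappa·D_add(fa)`), so kappa equals the flat CI when slopes
agree: kappa = 0.5 plants two-fold synergy, kappa = 1 the null.
Effect-dependent CI profiles (CI varying with fa) are produced by passing an
explicit mixture (dm, m) instead. All draws are seeded; per-series RNG
streams are derived from one seed, so a run is bit-reproducible.

What the generator does *not* emulate: mechanistic signalling, plate/batch
effects, heteroscedastic instrument noise, or dose-measurement error.
Passing tests therefore demonstrate correctness of the estimators and the
CI algebra under the stated noise conventions, not robustness to real
laboratory artefacts.

### Noisy-recovery calibration (frozen)

Under additive fa-noise σ = 0.05, 5-dose ladder, 2 replicates, and a steep
slope (m = 1.835), the refitted slope lands within 15% of truth in ≈ 75% of
500 seeded runs (median fitted slope unbiased). The rate is limited by the
unweighted-OLS variance at the ladder ends (fa ≈ 0.07 and 0.93), not by a
defect: replicate averaging (79%) and clipping (58%) do not improve it, and
a shallower slope m = 1.0 reaches 87%. The regression test freezes a ≥ 70%
bound plus a median-slope closeness check. The end-to-end interaction
recovery is much tighter because the CI at fa = 0.5 depends mainly on the
three fitted medians: a planted CI of 0.5 is recovered exactly noise-free
and with a median across 200 seeds well within ±0.1 at σ = 0.05.

## Pipeline and determinism

`run_full_analysis` drives everything from one YAML config: parse the
long-format dose–effect CSV (optionally converting µg/ml to µM through a
user-supplied compound registry — effective molar masses for mixtures must
be given explicitly, never inferred), fit the three series, build the
constant-ratio design, compute CI and DRI profiles, and write the bundle
(fits, CI profile, DRI, median-effect-plot coordinates, human-readable
summary). Floats are written at a fixed 4 decimals so identical config +
inputs give byte-identical output; the summary header records package
version, config hash, and seed.

## Problem sizes

The reference-table reproductions are closed-form evaluations (11- and
9-point grids, milliseconds). The simulation-based checks use 5-dose
ladders with 2 replicates; the noisy end-to-end check uses 200 seeds and
the recovery calibration 500, keeping the full suite under half a minute.

## Known limitations

- Constant-ratio, two-agent designs only; no checkerboard designs,
  ≥3-agent combinations, isobologram rendering, or CI confidence intervals.
- No uncertainty (bootstrap/Bayesian) on (Dm, m) in this version.
- Two independent experiments on the same agent are treated as independent
  fits and never merged.
- The strict classification band is a convention; near-1 CI values should
  be interpreted with the underlying fit quality (r²) in view.
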
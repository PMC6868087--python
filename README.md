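# synergyci

Quantitative two-drug synergy analysis by the median-effect / combination-index
method, built around the study design common in natural-product pharmacology:
two agents dosed alone and as a fixed-molar-ratio mixture, with the effect read
out as the fractional reduction of an inflammatory transcript (here, IL-1β
mRNA in LPS-stimulated human articular chondrocytes, quantified by qPCR).

It is written for pharmacologists who have three dose–effect series — each
agent alone and the constant-ratio mixture — and want a defensible, reproducible
answer to "is this combination synergistic, additive, or antagonistic, and at
which effect levels?"

## The model

Each series is fitted with the mass-action **median-effect equation**

```
fa / fu = (D / Dm)^m ,        fu = 1 - fa
```

where `fa` is the fraction affected at dose `D`, `Dm` the median-effect dose
(the IC50) and `m` a Hill-type coefficient. Taking logs gives the linear
*median-effect plot* `log10(fa/fu) = m·log10 D − m·log10 Dm`, fitted by
ordinary least squares; a four-parameter logistic fit is available as a
cross-check (with asymptotes fixed at 0 and 1 it is the same curve).

For a mixture at molar ratio `p1:p2` whose dose coordinate is the **total**
molar concentration, the **combination index** at any effect level `fa` is

```
CI(fa) = (D)1/(Dx)1 + (D)2/(Dx)2
```

with `(D)i` the ratio-split components of the mixture dose producing `fa`
and `(Dx)i` the single-agent doses producing the same `fa` alone.
`CI < 1` is synergism, `CI = 1` additivity (the Loewe null), `CI > 1`
antagonism. The companion dose-reduction index `DRI_i = (Dx)_i/(D)_i`
satisfies `1/DRI1 + 1/DRI2 = CI`.

The package also converts raw qPCR cycle thresholds into the fractional
effect via the 2^-ΔΔCT method, and ships a synthetic-data generator with a
known Loewe-additive null and a plantable interaction multiplier, so the whole
pipeline is testable end to end with no external data.

## Worked example

CI profile of a curcumin–β-caryophyllene combination (molar ratio 1:3.6) from
the three fitted median-effect parameter pairs — curcumin alone
(Dm = 13.57 µM, m = 1.38), β-caryophyllene alone (48.93 µM, 0.88), mixture
(28.28 µM total, 1.73):

```
$ synergyci --quiet ci --fit1 13.57,1.38 --fit2 48.93,0.88 \
    --fit12 28.28,1.73 --ratio 1:3.6 --fa-grid 0.1,0.3,0.5,0.7,0.9
fa,ci,d_total,d1,d2,dx1,dx2,diagnosis
0.1,2.167742726747576,7.941346386782813,1.7263796493006116,6.214966737482202,2.7612121031729173,4.029106320598732,antagonism
0.3,1.2389059576099126,17.329102120331818,3.767196113115613,13.561906007216207,7.3439549353439695,18.68184557779768,antagonism
0.5,0.9053685952858868,28.28,6.147826086956522,22.13217391304348,13.57,48.93,synergism
0.7,0.6819607682162878,46.15117358340586,10.032863822479534,36.11830976092633,25.074350485699867,128.15355367487388,synergism
0.9,0.46091977975998033,100.70816219918059,21.893078738952305,78.8150834602283,66.68987861830627,594.2123909115971,synergism
```

Reading the `fa = 0.5` row: 28.28 µM of the mixture (6.15 µM curcumin +
22.13 µM β-caryophyllene) halves IL-1β expression, whereas 13.57 µM curcumin
or 48.93 µM β-caryophyllene alone would be needed — CI = 6.15/13.57 +
22.13/48.93 ≈ 0.905 < 1, so less total drug achieves the effect than Loewe
additivity predicts. The combination is antagonistic at low effect levels
(CI = 2.17 at fa = 0.1) and increasingly synergistic from fa = 0.5 upward.

The same analysis can start from raw data: `synergyci readout` converts CT
tables to percent reduction, `synergyci fit` estimates (Dm, m) per agent from
a long-format CSV, and `synergyci report --config analysis.yaml` runs the
whole pipeline (fits, CI profile, DRI table, median-effect-plot coordinates,
summary) deterministically from one config. `synergyci simulate` generates
synthetic data with known ground truth.

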
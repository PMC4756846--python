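# gatefit

Quantitative characterization of two-inducer bacterial expression systems
from plate-reader, time-course and flow-cytometry data.

Inducible expression hosts that layer a transcriptional switch (inducer I,
e.g. IPTG acting on a *lac*-controlled promoter) on top of a translational
switch (inducer P, e.g. a riboswitch ligand) behave as leaky Boolean AND
gates. `gatefit` provides the forward models, global fitting and summary
statistics needed to characterize such systems: how tight the basal
expression is, how tuneable (analogue) versus switch-like (digital) the
dose response is, how much dual induction gains over a single inducer, and
how fast cells produce protein once induced. It is aimed at strain
engineers benchmarking expression hosts and at anyone fitting
dose-response surfaces from multiwell induction matrices.

## Models

Univariate titrations are fitted with a four-parameter logistic defined at
zero inducer,

```
y(x) = y0 + (ymax − y0) / (1 + (EC50/x)^n),        y(0) = y0,
```

from which EC quantiles follow in closed form,
`ECq = EC50 · (q/(1−q))^(1/n)`, and the dynamic range of ligand response

```
DRLR = EC90/EC10 = 81^(1/n).
```

Small DRLR (≈10) means a digital ON/OFF switch; large DRLR (hundreds)
means a precisely titratable analogue response.

Full bivariate induction matrices are fitted globally with a leaky AND
gate built from Hill occupancies `H(x; K, n) = x^n/(K^n + x^n)`:

```
y(I, P) = y0 + Δy · H(I; K1, n) · [ f1 + (1 − f1) · H(P; K2, n) ],
```

where `f1 ∈ [0, 1]` is the fraction of expression independent of P:
`f1 = 1` is a P-independent (I-only) system, `f1 = 0` a strict AND gate,
and `1/f1` is the enhancement from adding the second inducer at saturating
I. Corner outputs are digitized into truth tables at a 10% threshold
(D-OUT) and summarized by the synergy ratio
`A-OUT = (IP − UU) / ((I − UU) + (P − UU))`. Kinetics are linear fits of
RFU/OD over 0–5 h post induction; growth is log-linear (doubling time
ln 2/μ); a two-stage calibration (blot signal → ng via purified standards,
then RFU → ng) converts rates to volumetric productivities in mg/l/h.

## Worked example

```python
import numpy as np
from gatefit import (ANDGateParams, NoiseModel, default_levels,
                     simulate_matrix, fit_and_gate_global,
                     slice_matrix, fit_four_pl)

truth = ANDGateParams(y0=100, dy=10000, n=1.0, k1=120, k2=66, f1=1/12)
m = simulate_matrix(truth, i_levels=default_levels(120, 11),
                    p_levels=default_levels(66, 11),
                    replicates=1, noise=NoiseModel(kind="none"))
fit = fit_and_gate_global(m)
print(f"K2 = {fit.params.k2:.1f} uM, enhancement 1/f1 = {fit.enhancement:.1f}")

s = fit_four_pl(slice_matrix(m, "P", m.i_levels[-1]))
print(f"P-axis EC50 = {s.params.ec50:.1f} uM, DRLR = {s.drlr:.1f}")
```

prints

```
K2 = 66.0 uM, enhancement 1/f1 = 12.0
P-axis EC50 = 66.0 uM, DRLR = 81.0
```

— the global fit recovers the generating half-maximal P-axis constant
(66 μM) and the 12-fold dual-induction enhancement exactly on noiseless
data, and the saturating-I slice is itself an exact logistic in P with
midpoint K2 and unit Hill coefficient, hence DRLR = 81^(1/1) = 81.

The same workflow is available from the shell:

```
gatefit simulate --f1 0.0833 --cv 0 --out matrix.csv
gatefit fitgate matrix.csv --out fit.csv
gatefit truthtable matrix.csv
```

## Analysis drivers

The `analysis/` scripts run a complete synthetic benchmarking study of
three archetypal systems (dual transcriptional–translational control,
single-layer riboswitch control, transcription-only control):
`01_simulate_inputs.py` generates every input under `scratch/inputs/`,
then `02`–`06` fit titrations, fit the global gates, classify the logic,
extract kinetics/productivities and summarize single-cell homogeneity,
writing tables under `results/`.

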
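# glandeis

Virtual-tissue electrical impedance spectroscopy (EIS) of thyroid and
parathyroid glands: multiscale forward modelling of tetrapolar probe
measurements, global sensitivity analysis of tissue morphology, and a
separability study of the two tissue types from spectrum indices.

## The problem

During thyroidectomy the parathyroid glands are easily damaged because
they are hard to tell apart from thyroid tissue by eye. Tetrapolar EIS —
drive a small alternating current between two surface electrodes (I1,
V0), sense the potential on two others (V1, V2), report the transfer
impedance Z = (V₁ − V₂)/I over a frequency sweep — has been proposed as
an intraoperative discriminator, but in vivo spectra of the two glands
overlap heavily. This package builds parameterised "virtual tissue
constructs" of both glands, simulates their spectra across the natural
range of tissue morphology, and asks quantitatively *whether and under
what conditions the two tissues are separable*, with particular
attention to the superficial fascia layer that surgery may fail to
remove completely.

## The model

**Forward physics.** Each compartment is a linear conductive dielectric
with complex admittivity γ(f) = σ + j·2πf·ε₀·εᵣ. The quasi-static
potential obeys ∇·(γ∇V) = 0, discretised by node-centred finite volumes
on nonuniform tensor grids. Tissue is modelled at up to three scales:

* **micro** (cell scale): a periodic cuboid cell in an extracellular
  fluid gap `dECS`; the 8 nm membrane enters as a thin-layer per-area
  admittance γₘ/tₘ (meshed as an equivalent scaled layer), producing the
  β dispersion — the characteristic fall of Re Z through the kHz range;
* **meso** (follicle scale, thyroid only): a spherical colloid core
  wrapped in a single-cell epithelial shell carrying the homogenised
  micro-scale admittivity, packed in connective tissue;
* **macro** (tissue scale): a block under a four-electrode probe
  carrying the homogenised bulk, optionally capped by a fascia layer
  `dfascia`; the parathyroid gland is a finite block `dpara` embedded in
  connective-tissue background.

**Study design.** Morphological parameters follow published
distributions (six for thyroid, five for parathyroid); Latin hypercube
sampling places exactly one draw in each of N equiprobable strata per
parameter. Each draw yields a 14-point spectrum (76 Hz – 625 kHz),
parameterised by three indices: Z1 and Z14 (real impedance at the band
edges) and fmid (frequency where Re Z crosses (Z1+Z14)/2).

**Analysis.** Sensitivity is quantified by partial rank correlation
coefficients (PRCC) of each input against each index, with two-sided
t-test p-values and low/medium/high binning at |PRCC| = 0.4 and 0.7.
Separability is assessed by manual ROC threshold sweeps (TPR = TP/(TP+FN),
FPR = FP/(FP+TN); AUC by trapezoid, identical to the Mann–Whitney pair
statistic) in both label directions, and by 20-fold cross-validated
SVM / KNN / random-forest classification on (Z1, Z14, fmid).

A fast statistical surrogate generator (single-dispersion spectra with
monotone morphology links and a conductive fascia shunt) stands in for
the field solver in batch studies and tests; it is a fixture emulating
the simulator's sign structure, not tissue physics.

## Worked example

Draw a 100-run thyroid design (fascia included), generate spectra in
surrogate mode, extract indices and fit the sensitivity model:

```python
from glandeis import build_specs, lhs_sample, run_substudy
from glandeis.features import features_dataframe
from glandeis.sensitivity import PRCCAnalysis

design = lhs_sample(build_specs("thyroid", include_fascia=True), 100, seed=1,
                    gland="thyroid", include_fascia=True)
spectra = run_substudy(design, mode="surrogate", seed=2)
feats = features_dataframe(spectra)
print(PRCCAnalysis(design, feats).fit().summary())
```

```
PRCC sensitivity summary
========================
   Z1 ~ dfollicle  PRCC -0.86  p 2.4e-29  high
   Z1 ~ dECS       PRCC -0.79  p 7.9e-22  high
   Z1 ~ xcell      PRCC +0.64  p 4.7e-12  medium
   Z1 ~ dfascia    PRCC -0.38  p 1.8e-04  low
  Z14 ~ dfascia    PRCC -1.00  p 2.0e-103  high
  Z14 ~ dfollicle  PRCC +0.89  p 5.9e-33  high
  Z14 ~ xcell      PRCC -0.43  p 1.1e-05  medium
 fmid ~ dECS       PRCC +0.86  p 3.6e-29  high
 fmid ~ xcell      PRCC -0.84  p 6.6e-26  high
 fmid ~ dfollicle  PRCC +0.69  p 1.2e-14  medium
```

Reading: with a fascia layer present, the high-frequency impedance Z14
is governed almost entirely by fascia thickness (PRCC −1.00, a
conductive shunt), while the low-frequency impedance falls with follicle
size and extracellular-space thickness and the dispersion frequency
rises with `dECS` — the pattern that makes fascia removal decisive for
telling the glands apart.

The same stages are available from the shell:

```bash
glandeis sample --gland thyroid --fascia --n 100 --seed 1 --out design.csv
glandeis simulate --design design.csv --mode surrogate --out spectra.csv
glandeis features --spectra spectra.csv --out features.csv
glandeis sensitivity --design design.csv --features features.csv --out prcc.csv
glandeis full-study --outdir study/ --n 100 --seed 1 --surrogate
```

A single full field-solver spectrum (minutes at default resolution,
seconds at `--resolution coarse`) runs via `simulate --mode fe` or
`glandeis.simulate_spectrum(...)`.

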
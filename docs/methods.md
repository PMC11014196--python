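# Methods

## Scope and model hierarchy

The package predicts tetrapolar EIS spectra of thyroid and parathyroid
tissue from morphology alone: electrical material properties of the
compartments are held at baseline and only geometry varies. Tissue is
represented at two (parathyroid) or three (thyroid) scales, with each
scale homogenised into an effective complex admittivity that feeds the
next:

1. **Micro.** A periodic unit cell: a cuboid cell body (xcell × ycell ×
   zcell, µm) centred in an extracellular-fluid gap of thickness dECS.
   zcell is not part of the study design and is fixed to the gland's
   mean cell dimension (8.53 µm thyroid, 7.59 µm parathyroid), making
   the baseline cell isotropic. The plasma membrane (~8 nm) is never
   meshed; it enters as a per-area thin-layer admittance γₘ/tₘ,
   implemented as an equivalent meshed layer of thickness h = 4% of the
   smallest cell dimension whose admittivity is scaled by h/tₘ. This
   preserves the normal (series) admittance exactly; the tangential
   conduction it adds is γₘ·h/tₘ ≪ cytoplasmic, hence negligible. The
   homogenisation error of the equivalent layer scales with h.
2. **Meso** (thyroid only). A spherical follicle — colloid core plus an
   epithelial shell one cell layer thick (thickness = the sampled
   ycell), carrying the micro-scale effective admittivity — packed
   cubically in connective tissue with unit-cell edge dfollicle + dCT.
3. **Macro.** A 50 × 50 × 25 mm block (≥ 10 × the 5 mm electrode
   footprint; zero-flux outer boundaries approximate a half-space) under
   four collinear surface electrodes of 0.25 mm radius on a 1.5 mm
   pitch, drive and ground outermost. The probe dimensions are not
   published; the layout is configuration, not physics. Thyroid bulk
   fills the block (the follicular tissue is taken as the bulk, with no
   separate background); the parathyroid gland is a dpara-sized block
   centred under the probe in connective-tissue background. A fascia
   layer of thickness dfascia may cap the whole surface.

## Field solver

∇·(γ∇V) = 0 with γ(f) = σ + j·2πf·ε₀·εᵣ, discretised by node-centred
finite volumes on nonuniform tensor-product grids; each grid edge
carries the conductance of the four surrounding cell quadrants. With
material interfaces on grid planes, stacked slabs reproduce the series
(harmonic-mean) closed form to round-off, and a homogeneous composite
returns its material exactly. The sparse complex system is solved
directly (SuperLU); Dirichlet rows are substituted in place and the pure
Neumann macro problem is grounded at a far corner node.

* **Homogenisation** imposes a unit potential drop along the depth axis
  (zero-flux laterally — the symmetry condition of a mirror-symmetric
  periodic unit) and returns (average current density)/(average field).
  The composite is then treated as isotropic; cuboid and spherical units
  are near-isotropic, so one axis suffices.
* **Tetrapolar solve** injects ±1 A at drive/ground and reads
  Z = V(V1) − V(V2). Electrodes are either single nodes ("point", used
  against the analytic four-point half-space oracle) or equipotential
  node groups over each disc ("disc", the default). At the default mesh
  the homogeneous half-space solve is within 1.3% of the analytic
  formula (5% is the documented bound); the coarse preset, used for
  smoke runs, is within ~2%.
* **Resolution presets** (`coarse`/`default`/`fine`) set cells per
  feature at micro/meso scale and the under-electrode step and grading
  ratio at macro scale. A default-mesh multiscale spectrum solves in
  minutes; coarse in ~10 s.

Baseline compartment properties ship in
`src/glandeis/data/materials_default.yaml` with per-value provenance
notes. They are standard soft-tissue literature values (membrane
specific capacitance ≈ 1 µF/cm², interstitial fluid 1.2 S/m, connective
tissue 0.25 S/m, fascia more conductive at 0.45 S/m), fixed once at
model setup so the baseline constructs display the expected β
dispersion; the study never varies them. With these values the baseline
fall of Re Z is centred high in the band (fmid a few hundred kHz).
Because homogenised theoretical models are known to produce narrower,
higher-frequency dispersions than heterogeneous real tissue, we accept
this rather than force unphysical membrane properties.

## Study design

Six thyroid parameters (xcell, ycell, dECS, dfollicle, dCT, dfascia) and
five parathyroid parameters (xcell, ycell, dECS, dfascia, dpara) follow
the published uniform/normal distributions; excluding the fascia
compartment removes exactly dfascia, giving the four sub-studies
(gland × fascia), 100 draws each, 400 spectra of 14 frequencies. Each
sub-study draws a fresh independent design.

Latin hypercube sampling is implemented directly: each marginal's CDF is
split into n equiprobable intervals, one uniform draw per interval is
mapped through the inverse CDF, and column pairings are permuted by one
seeded generator consumed column-by-column in spec order
(bit-reproducible designs). Wide normal marginals (dfollicle's sd is
over half its mean) are left-truncated at the larger of the 0.1st
percentile and 1% of the mean; truncation is applied inside the inverse
CDF by remapping the quantile into the kept mass, which keeps the
stratification exact and every draw strictly positive.

The 14 measurement frequencies are fixed at 76 Hz and 625 kHz at the
ends; the instrument's intermediate frequencies are not published, so
the default grid is log-uniform and replaceable by configuration.

## Spectrum indices

Z1 and Z14 are Re Z at the first and last grid frequencies. fmid is the
frequency where Re Z crosses (Z1 + Z14)/2, interpolated linearly in
impedance and in log-frequency between the bracketing grid points
(dispersions are symmetric on a log-f axis; the alternative —
nearest-grid-point — changes fmid by at most half a grid step). Flat
spectra raise an explicit no-dispersion error; non-monotone spectra use
the first crossing from the low-frequency side and attach a warning.
Only the real part of the impedance feeds the analysis.

## Sensitivity (PRCC)

All inputs and the output are rank-transformed (ties → average ranks);
the PRCC is the Pearson correlation of the residuals after linearly
regressing the input's and the output's ranks on all other inputs'
ranks. Significance uses the two-sided t approximation with n − 2 − c
degrees of freedom (c controlled inputs). Association bins on |PRCC|:
low < 0.4, medium 0.4–0.7, high > 0.7; the published bins are open at
the boundaries, so exact boundary values are assigned to the lower bin
by convention. Report filters (on by default) keep p < 0.001 and
|PRCC| ≥ 0.3. PRCC is invariant under strictly monotone transforms of
any single variable, which the tests assert; at n = 100 the coefficient
estimates are not converged (a property of the design size, inherited
deliberately).

## Separability

Manual ROC: thresholds sweep the midpoints of adjacent sorted unique
pooled scores plus sentinels beyond both ends, so the curve is anchored
at (0,0) and (1,1); AUC is the trapezoidal area and equals the pair
statistic (#correctly ordered pairs + ½ ties)/(n_t·n_p), asserted on
random instances. Both label directions ("thyroid higher", "parathyroid
higher") are evaluated and the larger AUC reported with its direction.

Classification uses raw (Z1, Z14, fmid) — no scaling, selection or
preprocessing — with stratified 20-fold cross-validation on identical
fold splits for the three models (paired comparison; stratification
avoids single-class folds at these group sizes, and the fold seed is
explicit). Hyperparameters are library defaults: RBF SVM scored by its
decision function, KNN with k = 5 scored by the positive-class vote
fraction (it has no natural continuous score), random forest with 100
trees scored by class probability.

## Surrogate generator and emulated datasets

The surrogate maps a morphology draw to a single-dispersion curve
Re Z(f) = R∞ + (R0 − R∞)/(1 + (f/fc)^2α) via log-linear monotone links:
R0 falls with dECS and dfollicle, fc rises with dECS, Z14 tracks
dfollicle (thyroid) or ycell (parathyroid), and fascia acts as a
conductive shunt 1/(1/R + g·dfascia) that pulls R∞ down and compresses
the between-gland contrast, plus a mild pull-down of fc (stronger for
the smaller parathyroid gland). Log-normal parameter noise represents
unexplained morphological variance; optional per-point multiplicative
noise emulates measurement error. Base plateaus (thyroid 260→55 Ω,
parathyroid 360→130 Ω; fc 10 kHz vs 30 kHz) were chosen once so the
between-gland feature gaps sit in the regime the full model predicts:
parathyroid higher on all three indices, near-complete Z14 separation
without fascia, partial Z1 overlap.

The in-vivo emulator draws 53 thyroid and 42 parathyroid morphologies,
replaces the fascia prior by a random residual thickness
Uniform(0, 0.2) mm — incomplete surgical removal — and adds 5%
multiplicative noise. These stand-ins let every downstream stage run in
seconds; what passing surrogate-based tests shows is that the *analysis
machinery* recovers a known sign structure and separability ordering,
not that real tissue behaves this way. The surrogate is log-linear and
nearly interaction-free, so its PRCC magnitudes run higher than a
strongly nonlinear field-solver study would produce; only signs and
orderings are meaningful. Absolute impedance ranges of the in-vivo
pilot data are deliberately not reproduced.

## Numerical choices and degenerate inputs

Direct sparse solves with SuperLU (no iterative tolerance to tune);
non-finite potentials raise a solver error. dECS = 0 is allowed at the
micro scale (volume fraction 1). A follicle whose diameter does not
exceed two cell layers has no colloid core and is rejected. Batch runs
collect per-row failures and report them together with their row
indices — rows are never silently dropped. Effective-admittivity solves
are memoised per (geometry, frequency, resolution) key.

## Problem sizes used in checks

The reduced-scale sensitivity recovery runs 50–100 draws per sub-study
in surrogate mode; field-solver checks use the coarse preset (single
spectra and single-frequency solves), and the half-space oracle runs at
the default mesh. The acceptance script reruns the four 100-draw
sub-studies, both separability reports, the solver oracles and one
coarse baseline spectrum per gland in about half a minute.

## Known limitations

* The deposited computed-spectra dataset is an external download; the
  reproduction path (CSV adapter → indices → ROC/CV) is implemented and
  tested on generated data, but the published Table values can only be
  recomputed once that file is supplied at `data/deposited_spectra.csv`.
* Appendix baseline material values are not published; ours are
  literature defaults and shift absolute impedance levels (a non-goal).
* Voxelised spheres at the meso scale carry staircase error; the
  default grid resolves the epithelial shell with ~2 cells across.
* Electrode polarisation, contact impedance, inductive effects and
  probe misalignment are out of scope.
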
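# Baseline electrical material properties per tissue compartment.
#
# sigma   : conductivity, S/m
# eps_r   : relative permittivity, dimensionless
# thickness: physical thickness, m (membranes only; enters the model as a
#            thin-layer per-area admittance, never as a meshed volume)
#
# These are literature defaults in the ranges standard for soft-tissue
# dielectric modelling (Gabriel-type compilations and cell-suspension
# models), chosen so the baseline constructs show the expected beta
# dispersion in the kHz decades.  They are configuration, not code: swap
# this file to use a different baseline.

cytoplasm:
  sigma: 0.5
  eps_r: 60.0
  provenance: "intracellular medium of epithelial cells; sigma 0.3-1.0 S/m in cell-suspension dielectric models"

membrane:
  sigma: 1.0e-06
  eps_r: 9.0
  thickness: 8.0e-09
  provenance: "lipid bilayer ~8 nm; eps_r ~9 over 8 nm gives ~1 uF/cm^2 specific capacitance, the textbook value"

extracellular_fluid:
  sigma: 1.2
  eps_r: 80.0
  provenance: "interstitial fluid, slightly below physiological saline (1.5 S/m)"

colloid:
  sigma: 1.0
  eps_r: 80.0
  provenance: "thyroglobulin-rich follicular colloid, protein solution close to extracellular fluid"

connective_tissue:
  sigma: 0.25
  eps_r: 2000.0
  provenance: "wet fibrous connective tissue, low-frequency range of Gabriel-type compilations"

fascia:
  sigma: 0.45
  eps_r: 2000.0
  provenance: "loose areolar connective tissue; low cellularity and high fluid content make it more conductive than the glandular bulk"

background:
  sigma: 0.25
  eps_r: 2000.0
  provenance: "peri-glandular connective tissue surrounding the parathyroid; set equal to connective_tissue"
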
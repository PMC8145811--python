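{
  "_comment": "Default molecular volumes (A^3), X-ray scattering lengths (cm, electron count x Thomson radius 2.8179403e-13 cm) and solvent scattering length density (cm^-2) for SDS / C12E8 / beta-lactoglobulin modelling. Every key can be overridden by a user config.",
  "v_chain": 350.0,
  "v_head_sds": 60.0,
  "v_head_c12e8": 510.0,
  "protein_mass_da": 18300.0,
  "protein_vbar_cm3_per_g": 0.735,
  "electrons_chain": 97.0,
  "electrons_head_sds": 59.0,
  "electrons_head_c12e8": 201.0,
  "electrons_protein_per_da": 0.533,
  "rho_solvent": 9.42e10,
  "drho_m_protein": 2.0e10
}
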
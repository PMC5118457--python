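{
  "comment": "Tobacco ('standard') Rubisco kinetic constants and their exponential temperature responses: k(T) = k25 * exp(dHa/R * (1/298.15 - 1/T_K)), R = 8.314e-3 kJ mol-1 K-1. Two published variants: 'ci_basis' (intercellular-CO2 basis, infinite mesophyll conductance) and 'cc_basis' (chloroplastic-CO2 basis, finite mesophyll conductance). Values converted to partial pressures at 1 bar (1 ubar = 0.1 Pa; 1 umol mol-1 taken as 1 ubar).",
  "version": 1,
  "variants": {
    "ci_basis": {
      "Kc_Pa_25": 40.49,
      "Ko_kPa_25": 27.84,
      "gammastar_Pa_25": 4.275,
      "dHa_Kc_kJ_mol": 79.43,
      "dHa_Ko_kJ_mol": 36.38,
      "dHa_gammastar_kJ_mol": 37.83
    },
    "cc_basis": {
      "Kc_Pa_25": 27.238,
      "Ko_kPa_25": 16.582,
      "gammastar_Pa_25": 3.743,
      "dHa_Kc_kJ_mol": 80.99,
      "dHa_Ko_kJ_mol": 23.72,
      "dHa_gammastar_kJ_mol": 24.46
    }
  },
  "c4_standard": {
    "comment": "C4 model defaults at 25C: gamma* printed as the dimensionless ratio Gamma*/O; Kp held invariant with temperature; Rubisco constants scaled with the ci_basis tobacco activation energies.",
    "Kc_Pa_25": 65.0,
    "Ko_kPa_25": 45.0,
    "Kp_Pa_25": 8.0,
    "gammastar_ratio_25": 0.000193
  }
}
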
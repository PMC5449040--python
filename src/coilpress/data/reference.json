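{
  "format": "coilpress-reference",
  "version": 1,
  "description": "Random-coil backbone amide 15N/1HN pressure coefficients for Ac-Gly-Gly-X-Ala-NH2 tetrapeptides (0.1-200 MPa, 283 K, pH 6.7). delta0 in ppm at atmospheric pressure, B1 in ppm/GPa, B2 in ppm/GPa^2, oneJ_HN in Hz.",
  "entries": [
    {"residue": "Ala", "variant": "standard", "nucleus": "N15", "delta0": 124.39, "delta0_err": 0.01, "B1": 2.74, "B1_err": 0.03, "B2": -1.49, "B2_err": 0.16, "oneJ_HN": -97.5},
    {"residue": "Arg", "variant": "standard", "nucleus": "N15", "delta0": 121.00, "delta0_err": 0.01, "B1": 3.01, "B1_err": 0.04, "B2": -2.44, "B2_err": 0.21, "oneJ_HN": -95.5},
    {"residue": "Asn", "variant": "standard", "nucleus": "N15", "delta0": 119.12, "delta0_err": 0.01, "B1": 2.98, "B1_err": 0.17, "B2": -1.73, "B2_err": 0.82, "oneJ_HN": -95.9},
    {"residue": "Asp", "variant": "standard", "nucleus": "N15", "delta0": 120.94, "delta0_err": 0.01, "B1": 2.94, "B1_err": 0.07, "B2": -2.58, "B2_err": 0.36, "oneJ_HN": -96.0},
    {"residue": "Cys", "variant": "standard", "nucleus": "N15", "delta0": 119.21, "delta0_err": 0.01, "B1": 2.75, "B1_err": 0.08, "B2": -1.87, "B2_err": 0.41, "oneJ_HN": -96.0},
    {"residue": "Gln", "variant": "standard", "nucleus": "N15", "delta0": 120.25, "delta0_err": 0.01, "B1": 2.87, "B1_err": 0.06, "B2": -2.15, "B2_err": 0.29, "oneJ_HN": -93.5},
    {"residue": "Glu", "variant": "standard", "nucleus": "N15", "delta0": 120.95, "delta0_err": 0.01, "B1": 2.78, "B1_err": 0.17, "B2": -1.66, "B2_err": 0.83, "oneJ_HN": -99.5},
    {"residue": "Gly", "variant": "standard", "nucleus": "N15", "delta0": 109.22, "delta0_err": 0.01, "B1": 3.79, "B1_err": 0.08, "B2": -2.16, "B2_err": 0.37, "oneJ_HN": -96.9},
    {"residue": "His", "variant": "pH4.0", "nucleus": "N15", "delta0": 118.34, "delta0_err": 0.01, "B1": 3.42, "B1_err": 0.08, "B2": -2.86, "B2_err": 0.38, "oneJ_HN": -98.2},
    {"residue": "His", "variant": "pH8.5", "nucleus": "N15", "delta0": 120.33, "delta0_err": 0.01, "B1": 3.15, "B1_err": 0.10, "B2": -3.53, "B2_err": 0.50, "oneJ_HN": null},
    {"residue": "Ile", "variant": "standard", "nucleus": "N15", "delta0": 120.39, "delta0_err": 0.01, "B1": 2.35, "B1_err": 0.03, "B2": -1.89, "B2_err": 0.17, "oneJ_HN": -92.9},
    {"residue": "Leu", "variant": "standard", "nucleus": "N15", "delta0": 122.07, "delta0_err": 0.01, "B1": 2.65, "B1_err": 0.10, "B2": -2.92, "B2_err": 0.48, "oneJ_HN": -96.2},
    {"residue": "Lys", "variant": "standard", "nucleus": "N15", "delta0": 121.29, "delta0_err": 0.01, "B1": 3.00, "B1_err": 0.03, "B2": -2.24, "B2_err": 0.13, "oneJ_HN": -94.7},
    {"residue": "Met", "variant": "standard", "nucleus": "N15", "delta0": 120.17, "delta0_err": 0.01, "B1": 2.76, "B1_err": 0.05, "B2": -1.89, "B2_err": 0.22, "oneJ_HN": -92.7},
    {"residue": "Phe", "variant": "standard", "nucleus": "N15", "delta0": 120.62, "delta0_err": 0.01, "B1": 3.01, "B1_err": 0.04, "B2": -3.65, "B2_err": 0.19, "oneJ_HN": -95.5},
    {"residue": "Pro", "variant": "trans", "nucleus": "N15", "delta0": 134.78, "delta0_err": 0.01, "B1": 2.45, "B1_err": 0.02, "B2": -1.76, "B2_err": 0.10, "oneJ_HN": null},
    {"residue": "Pro", "variant": "cis", "nucleus": "N15", "delta0": 135.03, "delta0_err": 0.01, "B1": 1.36, "B1_err": 0.02, "B2": -0.38, "B2_err": 0.10, "oneJ_HN": null},
    {"residue": "Ser", "variant": "standard", "nucleus": "N15", "delta0": 116.27, "delta0_err": 0.01, "B1": 3.41, "B1_err": 0.15, "B2": -2.46, "B2_err": 0.70, "oneJ_HN": -95.7},
    {"residue": "Thr", "variant": "standard", "nucleus": "N15", "delta0": 114.14, "delta0_err": 0.01, "B1": 3.28, "B1_err": 0.05, "B2": -2.36, "B2_err": 0.24, "oneJ_HN": -93.8},
    {"residue": "Trp", "variant": "standard", "nucleus": "N15", "delta0": 121.43, "delta0_err": 0.01, "B1": 3.35, "B1_err": 0.03, "B2": -2.90, "B2_err": 0.17, "oneJ_HN": -95.5},
    {"residue": "Tyr", "variant": "standard", "nucleus": "N15", "delta0": 120.33, "delta0_err": 0.01, "B1": 3.56, "B1_err": 0.07, "B2": -4.52, "B2_err": 0.32, "oneJ_HN": -93.9},
    {"residue": "Val", "variant": "standard", "nucleus": "N15", "delta0": 119.41, "delta0_err": 0.01, "B1": 2.32, "B1_err": 0.02, "B2": -1.70, "B2_err": 0.12, "oneJ_HN": -95.0},
    {"residue": "Ala", "variant": "standard", "nucleus": "H1N", "delta0": 8.368, "delta0_err": 0.001, "B1": 0.45, "B1_err": 0.02, "B2": -0.15, "B2_err": 0.08, "oneJ_HN": null},
    {"residue": "Arg", "variant": "standard", "nucleus": "H1N", "delta0": 8.342, "delta0_err": 0.001, "B1": 0.48, "B1_err": 0.02, "B2": -0.22, "B2_err": 0.10, "oneJ_HN": null},
    {"residue": "Asn", "variant": "standard", "nucleus": "H1N", "delta0": 8.503, "delta0_err": 0.001, "B1": 0.50, "B1_err": 0.03, "B2": -0.42, "B2_err": 0.14, "oneJ_HN": null},
    {"residue": "Asp", "variant": "standard", "nucleus": "H1N", "delta0": 8.433, "delta0_err": 0.001, "B1": 0.56, "B1_err": 0.02, "B2": -0.48, "B2_err": 0.09, "oneJ_HN": null},
    {"residue": "Cys", "variant": "standard", "nucleus": "H1N", "delta0": 8.418, "delta0_err": 0.001, "B1": 0.55, "B1_err": 0.01, "B2": -0.49, "B2_err": 0.05, "oneJ_HN": null},
    {"residue": "Gln", "variant": "standard", "nucleus": "H1N", "delta0": 8.433, "delta0_err": 0.001, "B1": 0.44, "B1_err": 0.03, "B2": -0.17, "B2_err": 0.13, "oneJ_HN": null},
    {"residue": "Glu", "variant": "standard", "nucleus": "H1N", "delta0": 8.539, "delta0_err": 0.001, "B1": 0.25, "B1_err": 0.02, "B2": -0.03, "B2_err": 0.08, "oneJ_HN": null},
    {"residue": "Gly", "variant": "standard", "nucleus": "H1N", "delta0": 8.449, "delta0_err": 0.001, "B1": 0.24, "B1_err": 0.01, "B2": -0.10, "B2_err": 0.06, "oneJ_HN": null},
    {"residue": "His", "variant": "pH4.0", "nucleus": "H1N", "delta0": 8.484, "delta0_err": 0.001, "B1": 0.51, "B1_err": 0.01, "B2": -0.47, "B2_err": 0.06, "oneJ_HN": null},
    {"residue": "Ile", "variant": "standard", "nucleus": "H1N", "delta0": 8.154, "delta0_err": 0.001, "B1": 0.64, "B1_err": 0.03, "B2": -0.64, "B2_err": 0.14, "oneJ_HN": null},
    {"residue": "Leu", "variant": "standard", "nucleus": "H1N", "delta0": 8.279, "delta0_err": 0.001, "B1": 0.52, "B1_err": 0.02, "B2": -0.50, "B2_err": 0.12, "oneJ_HN": null},
    {"residue": "Lys", "variant": "standard", "nucleus": "H1N", "delta0": 8.317, "delta0_err": 0.001, "B1": 0.55, "B1_err": 0.02, "B2": -0.49, "B2_err": 0.10, "oneJ_HN": null},
    {"residue": "Met", "variant": "standard", "nucleus": "H1N", "delta0": 8.398, "delta0_err": 0.001, "B1": 0.49, "B1_err": 0.02, "B2": -0.31, "B2_err": 0.10, "oneJ_HN": null},
    {"residue": "Phe", "variant": "standard", "nucleus": "H1N", "delta0": 8.263, "delta0_err": 0.001, "B1": 0.55, "B1_err": 0.02, "B2": -0.68, "B2_err": 0.10, "oneJ_HN": null},
    {"residue": "Ser", "variant": "standard", "nucleus": "H1N", "delta0": 8.434, "delta0_err": 0.001, "B1": 0.64, "B1_err": 0.05, "B2": -0.65, "B2_err": 0.26, "oneJ_HN": null},
    {"residue": "Thr", "variant": "standard", "nucleus": "H1N", "delta0": 8.269, "delta0_err": 0.001, "B1": 0.75, "B1_err": 0.02, "B2": -0.56, "B2_err": 0.11, "oneJ_HN": null},
    {"residue": "Trp", "variant": "standard", "nucleus": "H1N", "delta0": 8.129, "delta0_err": 0.001, "B1": 0.58, "B1_err": 0.02, "B2": -0.42, "B2_err": 0.11, "oneJ_HN": null},
    {"residue": "Tyr", "variant": "standard", "nucleus": "H1N", "delta0": 8.190, "delta0_err": 0.001, "B1": 0.67, "B1_err": 0.05, "B2": -0.82, "B2_err": 0.25, "oneJ_HN": null},
    {"residue": "Val", "variant": "standard", "nucleus": "H1N", "delta0": 8.232, "delta0_err": 0.001, "B1": 0.58, "B1_err": 0.02, "B2": -0.21, "B2_err": 0.08, "oneJ_HN": null}
  ]
}
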
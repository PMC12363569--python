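{
  "version": "1.0",
  "comment": "Per-residue physicochemical scales over the 20 canonical amino acids. kyte_doolittle: hydropathy (Kyte & Doolittle); hopp_woods: hydrophilicity (Hopp & Woods); chou_hydrophobicity: normalized hydrophobicity used by pseudo amino acid composition; side_chain_mass: side-chain mass in Da; grantham_polarity / grantham_volume / grantham_composition: the three properties underlying Grantham's chemical distance; isoelectric_point: residue pI.",
  "scales": {
    "kyte_doolittle": {
      "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
      "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
      "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
      "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3
    },
    "hopp_woods": {
      "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
      "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
      "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
      "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3
    },
    "chou_hydrophobicity": {
      "A": 0.62, "C": 0.29, "D": -0.9, "E": -0.74, "F": 1.19,
      "G": 0.48, "H": -0.4, "I": 1.38, "K": -1.5, "L": 1.06,
      "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
      "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26
    },
    "side_chain_mass": {
      "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
      "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
      "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
      "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0
    },
    "grantham_polarity": {
      "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
      "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
      "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
      "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2
    },
    "grantham_volume": {
      "A": 31.0, "C": 55.0, "D": 54.0, "E": 83.0, "F": 132.0,
      "G": 3.0, "H": 96.0, "I": 111.0, "K": 119.0, "L": 111.0,
      "M": 105.0, "N": 56.0, "P": 32.5, "Q": 85.0, "R": 124.0,
      "S": 32.0, "T": 61.0, "V": 84.0, "W": 170.0, "Y": 136.0
    },
    "grantham_composition": {
      "A": 0.0, "C": 2.75, "D": 1.38, "E": 0.92, "F": 0.0,
      "G": 0.74, "H": 0.58, "I": 0.0, "K": 0.33, "L": 0.0,
      "M": 0.0, "N": 1.33, "P": 0.39, "Q": 0.89, "R": 0.65,
      "S": 1.42, "T": 0.71, "V": 0.0, "W": 0.13, "Y": 0.2
    },
    "isoelectric_point": {
      "A": 6.0, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48,
      "G": 5.97, "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98,
      "M": 5.74, "N": 5.41, "P": 6.3, "Q": 5.65, "R": 10.76,
      "S": 5.68, "T": 5.66, "V": 5.96, "W": 5.89, "Y": 5.66
    }
  }
}
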
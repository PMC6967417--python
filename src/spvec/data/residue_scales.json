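{
  "version": 1,
  "description": "Per-residue property scales for the 20 standard amino acids.",
  "scales": {
    "mass": {
      "description": "Monoisotopic residue mass (Da)",
      "values": {
        "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
        "C": 103.00919, "Q": 128.05858, "E": 129.04259, "G": 57.02146,
        "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
        "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
        "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841
      }
    },
    "volume": {
      "description": "Zamyatnin residue volume (cubic Angstrom)",
      "values": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1,
        "C": 108.5, "Q": 143.8, "E": 138.4, "G": 60.1,
        "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
        "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0,
        "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0
      }
    },
    "polarity": {
      "description": "Grantham polarity",
      "values": {
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0,
        "C": 5.5, "Q": 10.5, "E": 12.3, "G": 9.0,
        "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
        "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2,
        "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9
      }
    },
    "hydrophobicity": {
      "description": "Kyte-Doolittle hydropathy index",
      "values": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5,
        "C": 2.5, "Q": -3.5, "E": -3.5, "G": -0.4,
        "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8,
        "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
      }
    }
  }
}
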
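{
  "schema_version": 1,
  "description": "Acquisition presets: dual-source tube-voltage pairs and effective tube current-time products (mAs, system A / system B) for the spectral-calibration size series and for the quantification scans at both dose modes.",
  "voltage_pairs": {
    "70/150Sn": ["70", "150Sn"],
    "80/150Sn": ["80", "150Sn"],
    "100/150Sn": ["100", "150Sn"],
    "80/140": ["80", "140"]
  },
  "calibration_diameters_cm": [10, 15, 20, 25, 30, 35],
  "calibration_tube_current_mas": {
    "70/150Sn": {"10": [16, 16], "15": [18, 16], "20": [37, 22], "25": [80, 36], "30": [180, 64], "35": [410, 95]},
    "80/150Sn": {"10": [16, 16], "15": [16, 16], "20": [23, 22], "25": [45, 36], "30": [95, 60], "35": [202, 95]},
    "100/150Sn": {"10": [16, 16], "15": [20, 16], "20": [34, 22], "25": [60, 36], "30": [109, 60], "35": [195, 95]},
    "80/140": {"10": [16, 16], "15": [16, 16], "20": [16, 16], "25": [30, 16], "30": [65, 16], "35": [142, 24]}
  },
  "quantification_tube_current_mas": {
    "70/150Sn": {"clinical": [212, 55], "high": [1083, 271]},
    "80/150Sn": {"clinical": [105, 54], "high": [1083, 542]},
    "100/150Sn": {"clinical": [60, 53], "high": [840, 420]},
    "80/140": {"clinical": [73, 18], "high": [997, 181]}
  }
}
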
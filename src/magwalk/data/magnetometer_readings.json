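{
  "exp1_before_180": {"x": 26.824, "y": -0.022, "z": 39.922, "declination": 0.0, "inclination": 56.0, "intensity": 48.095, "coil_on": false, "alteration_deg": 180.0},
  "exp1_after_180": {"x": 27.241, "y": 0.161, "z": 39.767, "declination": 179.6, "inclination": 55.5, "intensity": 48.193, "coil_on": true, "alteration_deg": 180.0},
  "exp2_before_120": {"x": 26.551, "y": 0.015, "z": 37.955, "declination": 0.0, "inclination": 55.0, "intensity": 46.323, "coil_on": false, "alteration_deg": 120.0},
  "exp2_after_120": {"x": -13.130, "y": 25.035, "z": 37.505, "declination": 118.1, "inclination": 53.0, "intensity": 46.957, "coil_on": true, "alteration_deg": 120.0}
}
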
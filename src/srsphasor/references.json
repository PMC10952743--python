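{
  "_comment": "Packaged Raman reference library. Peak shapes are nominal; for components with a non-null rie_height the amplitudes are rescaled at load time so the baseline-corrected band height equals rie_height x EdU's band height on a 1 cm^-1 grid. Sub-peak positions/widths of the split B-H envelope and all fingerprint modes are documented free parameters, not measured values.",
  "edu_band_window": [2090, 2150],
  "components": [
    {
      "name": "edu",
      "band_window": [2090, 2150],
      "rie_height": 1.0,
      "peaks": [
        {"center": 2120.0, "fwhm": 14.0, "amplitude": 1.0, "shape": "gaussian"}
      ]
    },
    {
      "name": "metallacarborane",
      "band_window": [2480, 2650],
      "rie_height": 3.0,
      "peaks": [
        {"center": 2525.0, "fwhm": 55.0, "amplitude": 0.75, "shape": "gaussian"},
        {"center": 2570.0, "fwhm": 50.0, "amplitude": 1.0, "shape": "gaussian"},
        {"center": 2615.0, "fwhm": 45.0, "amplitude": 0.65, "shape": "gaussian"},
        {"center": 635.0, "fwhm": 16.0, "amplitude": 0.25, "shape": "lorentzian"},
        {"center": 250.0, "fwhm": 30.0, "amplitude": 0.2, "shape": "lorentzian"},
        {"center": 205.0, "fwhm": 20.0, "amplitude": 0.2, "shape": "lorentzian"}
      ]
    },
    {
      "name": "ortho_carborane",
      "band_window": [2480, 2650],
      "rie_height": 2.0,
      "peaks": [
        {"center": 2560.0, "fwhm": 45.0, "amplitude": 1.0, "shape": "gaussian"},
        {"center": 2600.0, "fwhm": 40.0, "amplitude": 0.55, "shape": "gaussian"},
        {"center": 725.0, "fwhm": 18.0, "amplitude": 0.2, "shape": "lorentzian"}
      ]
    },
    {
      "name": "butadiyne_am_ester",
      "band_window": [2190, 2250],
      "rie_height": 12.0,
      "peaks": [
        {"center": 2220.0, "fwhm": 18.0, "amplitude": 1.0, "shape": "gaussian"}
      ]
    },
    {
      "name": "butadiyne_imidazole",
      "band_window": [2190, 2250],
      "rie_height": 12.0,
      "peaks": [
        {"center": 2220.0, "fwhm": 18.0, "amplitude": 1.0, "shape": "gaussian"}
      ]
    },
    {
      "name": "stearic_d35",
      "band_window": [2070, 2135],
      "rie_height": 0.8,
      "peaks": [
        {"center": 2102.0, "fwhm": 22.0, "amplitude": 1.0, "shape": "gaussian"},
        {"center": 2195.0, "fwhm": 28.0, "amplitude": 0.25, "shape": "gaussian"}
      ]
    },
    {
      "name": "cosan_d2",
      "band_window": [2245, 2290],
      "rie_height": null,
      "peaks": [
        {"center": 2260.4, "fwhm": 10.0, "amplitude": 1.0, "shape": "gaussian"},
        {"center": 2273.4, "fwhm": 10.0, "amplitude": 0.8, "shape": "gaussian"}
      ]
    },
    {
      "name": "protein_ch3",
      "band_window": [2800, 3050],
      "rie_height": null,
      "peaks": [
        {"center": 2930.0, "fwhm": 45.0, "amplitude": 1.0, "shape": "gaussian"},
        {"center": 2880.0, "fwhm": 50.0, "amplitude": 0.4, "shape": "gaussian"}
      ]
    },
    {
      "name": "lipid_ch2",
      "band_window": [2800, 3050],
      "rie_height": null,
      "peaks": [
        {"center": 2851.0, "fwhm": 35.0, "amplitude": 1.0, "shape": "gaussian"},
        {"center": 2890.0, "fwhm": 55.0, "amplitude": 0.55, "shape": "gaussian"},
        {"center": 2930.0, "fwhm": 40.0, "amplitude": 0.22, "shape": "gaussian"}
      ]
    }
  ]
}
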
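{
  "description": "Modeled emission spectra of common street-lighting technologies. Each class is a sum of Gaussian emission lines [center_nm, amplitude, sigma_nm] and broad Gaussian continua [center_nm, amplitude, sigma_nm], evaluated on the package wavelength grid and normalized to unit total power. These are synthetic parametric stand-ins for measured lamp spectra; substitute measured curves via CSV where available.",
  "classes": {
    "lps": {
      "label": "low-pressure sodium",
      "lines": [[589.3, 1.0, 2.0]],
      "continua": []
    },
    "hps": {
      "label": "high-pressure sodium",
      "lines": [
        [498.0, 0.10, 3.0],
        [568.3, 0.60, 4.0],
        [589.0, 1.00, 8.0],
        [615.4, 0.50, 5.0],
        [668.0, 0.15, 5.0]
      ],
      "continua": [[600.0, 0.10, 80.0]]
    },
    "mercury": {
      "label": "mercury vapor",
      "lines": [
        [404.7, 0.40, 2.0],
        [435.8, 0.70, 2.0],
        [546.1, 1.00, 2.0],
        [578.0, 0.80, 3.0]
      ],
      "continua": [[560.0, 0.05, 90.0]]
    },
    "metal_halide": {
      "label": "metal halide",
      "lines": [
        [435.8, 0.45, 2.5],
        [546.1, 0.70, 2.5],
        [578.0, 0.55, 3.0],
        [589.0, 0.40, 4.0]
      ],
      "continua": [[540.0, 0.45, 100.0]]
    },
    "fluorescent": {
      "label": "triphosphor fluorescent",
      "lines": [
        [435.8, 0.50, 2.5],
        [487.0, 0.30, 4.0],
        [546.1, 1.00, 3.0],
        [611.6, 0.80, 4.0]
      ],
      "continua": [[520.0, 0.12, 90.0]]
    },
    "led_3000k": {
      "label": "white LED 3000 K",
      "lines": [],
      "continua": [
        [450.0, 0.35, 12.0],
        [600.0, 1.00, 60.0]
      ]
    },
    "led_4000k": {
      "label": "white LED 4000 K",
      "lines": [],
      "continua": [
        [450.0, 0.60, 12.0],
        [580.0, 1.00, 55.0]
      ]
    }
  }
}
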
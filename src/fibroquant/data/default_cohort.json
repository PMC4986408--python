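{
  "ratio_mean": {
    "anterolateral_calf": {
      "lean_youth": 0.03,
      "lean_aged": 0.06,
      "obese_youth": 0.23,
      "obese_aged": 0.30
    },
    "posterior_calf": {
      "lean_youth": 0.06,
      "lean_aged": 0.13,
      "obese_youth": 0.23,
      "obese_aged": 0.31
    },
    "plantar": {
      "lean_youth": 0.02,
      "lean_aged": 0.09,
      "obese_youth": 0.244,
      "obese_aged": 0.33
    }
  },
  "ratio_sem": {
    "anterolateral_calf": {
      "lean_youth": 0.004,
      "lean_aged": 0.0104,
      "obese_youth": 0.0071,
      "obese_aged": 0.006
    },
    "posterior_calf": {
      "lean_youth": 0.003,
      "lean_aged": 0.003,
      "obese_youth": 0.003,
      "obese_aged": 0.004
    },
    "plantar": {
      "lean_youth": 0.002,
      "lean_aged": 0.017,
      "obese_youth": 0.006,
      "obese_aged": 0.007
    }
  },
  "n_per_group": 24,
  "bilateral_asymmetry_sd": 0.01,
  "seed": null,
  "phantom": {
    "image_height": 128,
    "image_width": 128,
    "muscle_grey_mean": 80.0,
    "fibrous_grey_mean": 180.0,
    "grey_noise_sd": 5.0,
    "blob_scale": 4.0,
    "roi_margin": 8,
    "background_grey": 10.0
  }
}
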
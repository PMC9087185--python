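{
  "outdir": "scratch/pipeline_out",
  "seed": 1,
  "synth": {
    "years": 8,
    "noise_sd": 0.02
  },
  "fit": {
    "n_starts": 1,
    "guess_scale": 1.2
  },
  "sweeps": [
    {"parameter": "alpha", "values": [0.022, 0.044, 0.066], "t_end": 600, "n_points": 121},
    {"parameter": "m_f", "multipliers": [0.5, 1.0, 1.5], "t_end": 600, "n_points": 121}
  ]
}
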
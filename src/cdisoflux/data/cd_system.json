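{
  "comment": "Placeholder Cd isotope system for the 110/111/113/114 subset. Reference ratios follow natural Cd abundances; the 111Cd-113Cd double-spike composition is illustrative, not a certified value. Edit freely for a real calibration.",
  "isotope_masses": [109.9030066, 110.9041829, 112.9044081, 113.9033589],
  "reference_ratios": [1.024820, 0.978383, 2.300240],
  "spike_ratios": [24.0, 23.5, 1.5],
  "spike_conc_ng_per_g": 100.0
}
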
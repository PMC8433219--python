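{
  "drug_name": "isradipine",
  "concentration_unit": "nM",
  "doses": [4.1, 12.3, 37.4, 111.0, 333.0],
  "comment": "Ca2+ channel blocker. Accelerates firing (rate endpoint +30%, qualitative), shortens the second repolarization wave (E6-E8 duration -70.54% at the top dose), and strongly suppresses contraction at high doses (MB amplitude -95% at 333 nM), which makes the MB bump vanish into the noise floor. max_effect = endpoint / Hill(333 nM; ec50 37.4, n 2).",
  "effects": [
    {"target": "rate", "max_effect": 0.3037842166, "ec50": 37.4, "hill_n": 2.0, "onset_tau": 5.0},
    {"target": "E6E8", "max_effect": -0.7142979547, "ec50": 37.4, "hill_n": 2.0, "onset_tau": 5.0},
    {"target": "mb_amplitude", "max_effect": -0.9619833527, "ec50": 37.4, "hill_n": 2.0, "onset_tau": 5.0}
  ]
}
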
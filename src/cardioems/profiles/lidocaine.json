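{
  "drug_name": "lidocaine",
  "concentration_unit": "uM",
  "doses": [1.23, 3.7, 11.1, 33.3, 100.0],
  "comment": "Na+ channel blocker. Endpoint effect sizes at the top dose (100 uM): rate -57.58%, em_delay +72.93% (chosen so the paired E1-M2 / E4-M2 durations prolong by 26.5% / 33.66% with the default templates); amplitude reductions are qualitative. max_effect = endpoint / Hill(100 uM; ec50 11.1, n 2) so the modifier at 100 uM equals the endpoint exactly.",
  "effects": [
    {"target": "rate", "max_effect": -0.5828944318, "ec50": 11.1, "hill_n": 2.0, "onset_tau": 5.0},
    {"target": "em_delay", "max_effect": 0.7382857053, "ec50": 11.1, "hill_n": 2.0, "onset_tau": 5.0},
    {"target": "fp_first_amplitude", "max_effect": -0.35431235, "ec50": 11.1, "hill_n": 2.0, "onset_tau": 5.0},
    {"target": "fp_second_amplitude", "max_effect": -0.3036963, "ec50": 11.1, "hill_n": 2.0, "onset_tau": 5.0},
    {"target": "mb_amplitude", "max_effect": -0.4049284, "ec50": 11.1, "hill_n": 2.0, "onset_tau": 5.0}
  ]
}
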
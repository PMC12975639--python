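{
  "system": "cyp450",
  "description": "Microsomal drug metabolism by cytochrome P450 + CPR + cyt b5: classical five-step serial binding cycle vs murburn unordered DRS interactions.",
  "source": "encoded from published comparison; classical index 1/160 = 1/5 selection x (1/2)^5",
  "classical": {
    "name": "CYP classical (P450cam-type)",
    "shape_change": 1,
    "serial": 1,
    "n_steps": 5,
    "irreducible_complexity": 1,
    "molecularity": 5,
    "long_range_et": 1,
    "es_complex": 1,
    "scheme": {"n_events": 5, "selection_factors": [5], "parallel_modes": 1}
  },
  "murburn": {
    "name": "CYP murburn",
    "shape_change": 0,
    "serial": 0,
    "n_steps": 4,
    "irreducible_complexity": 0,
    "molecularity": 2,
    "long_range_et": 0,
    "es_complex": 0,
    "scheme": {"n_events": 4, "selection_factors": [], "parallel_modes": 4}
  }
}
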
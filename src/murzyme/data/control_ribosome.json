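{
  "system": "control_ribosome",
  "description": "Classical control: mRNA translation by the ribosome. High-fidelity codon-directed synthesis favors the classical account; a hypothetical DRS-mediated account is encoded for contrast. Synthetic control encoding.",
  "classical": {
    "name": "ribosome classical",
    "shape_change": 1,
    "serial": 1,
    "n_steps": 3,
    "irreducible_complexity": 0,
    "molecularity": 3,
    "long_range_et": 0,
    "es_complex": 1,
    "scheme": {"n_events": 3, "selection_factors": [], "parallel_modes": 1}
  },
  "murburn": {
    "name": "ribosome murburn (hypothetical)",
    "shape_change": 0,
    "serial": 0,
    "n_steps": 25,
    "irreducible_complexity": 0,
    "molecularity": 5,
    "long_range_et": 1,
    "es_complex": 0,
    "scheme": {"n_events": 15, "selection_factors": [20], "parallel_modes": 1}
  },
  "classical_assertions": [
    "SUBSTRATE_SELECTIVITY",
    "SUBSTRATE_BOUND_AT_ACTIVE_SITE"
  ]
}
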
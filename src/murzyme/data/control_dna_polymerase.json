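{
  "system": "control_dna_polymerase",
  "description": "Classical control: template-directed DNA replication. The active-site account is the simpler, internally consistent model; a hypothetical DRS-mediated account of high-fidelity copying is encoded for contrast. Synthetic control encoding.",
  "classical": {
    "name": "DNA polymerase classical",
    "shape_change": 1,
    "serial": 1,
    "n_steps": 2,
    "irreducible_complexity": 0,
    "molecularity": 2,
    "long_range_et": 0,
    "es_complex": 1,
    "scheme": {"n_events": 2, "selection_factors": [], "parallel_modes": 1}
  },
  "murburn": {
    "name": "DNA polymerase murburn (hypothetical)",
    "shape_change": 0,
    "serial": 0,
    "n_steps": 20,
    "irreducible_complexity": 0,
    "molecularity": 4,
    "long_range_et": 1,
    "es_complex": 0,
    "scheme": {"n_events": 12, "selection_factors": [4], "parallel_modes": 1}
  },
  "classical_assertions": [
    "SUBSTRATE_SELECTIVITY",
    "SUBSTRATE_BOUND_AT_ACTIVE_SITE"
  ]
}
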
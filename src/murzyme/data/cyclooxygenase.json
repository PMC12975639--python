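{
  "system": "cyclooxygenase",
  "description": "Membrane-embedded cyclooxygenase (COX1/2) pain-hormone synthesis: classical two-site serial cycle vs murburn DRS collisions.",
  "source": "classical event decomposition reverse-engineered: 6 half-events and two one-of-three selections reproduce the printed 1/576; synthetic inference, not printed",
  "classical": {
    "name": "cyclooxygenase classical (Janus)",
    "shape_change": 1,
    "serial": 1,
    "n_steps": 16,
    "irreducible_complexity": 1,
    "molecularity": 3,
    "long_range_et": 1,
    "es_complex": 1,
    "scheme": {"n_events": 6, "selection_factors": [3, 3], "parallel_modes": 1}
  },
  "murburn": {
    "name": "cyclooxygenase murburn",
    "shape_change": 0,
    "serial": 0,
    "n_steps": 4,
    "irreducible_complexity": 0,
    "molecularity": 2,
    "long_range_et": 0,
    "es_complex": 0,
    "scheme": {"n_events": 4, "selection_factors": [], "parallel_modes": 2}
  }
}
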
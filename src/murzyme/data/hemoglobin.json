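{
  "system": "hemoglobin",
  "description": "Erythrocyte hemoglobin: classical allosteric O2 transport only vs murburn superoxide-assisted ATP synthesis alongside transport.",
  "source": "no numeric indices printed for this system; both schemes encoded with two binding/detachment half-events, murburn flagged multi-mode; synthetic encoding",
  "classical": {
    "name": "hemoglobin classical O2 transport",
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
    "name": "hemoglobin murburn",
    "shape_change": 0,
    "serial": 0,
    "n_steps": 2,
    "irreducible_complexity": 0,
    "molecularity": 2,
    "long_range_et": 0,
    "es_complex": 0,
    "scheme": {"n_events": 2, "selection_factors": [], "parallel_modes": 2}
  }
}
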
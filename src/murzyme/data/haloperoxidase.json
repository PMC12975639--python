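{
  "system": "haloperoxidase",
  "description": "Soluble heme-haloperoxidase (CPO/catalase/HRP family): classical Compound-I active-site cycle vs murburn DRS-mediated milieu reactions.",
  "source": "encoded from published comparison",
  "classical": {
    "name": "haloperoxidase lock-and-key",
    "shape_change": 1,
    "serial": 1,
    "n_steps": 3,
    "irreducible_complexity": 0,
    "molecularity": 2,
    "long_range_et": 0,
    "es_complex": 1,
    "scheme": {"n_events": 3, "selection_factors": [], "parallel_modes": 1}
  },
  "murburn": {
    "name": "haloperoxidase murburn",
    "shape_change": 0,
    "serial": 0,
    "n_steps": 2,
    "irreducible_complexity": 0,
    "molecularity": 2,
    "long_range_et": 0,
    "es_complex": 0,
    "scheme": {"n_events": 3, "selection_factors": [], "parallel_modes": 4}
  }
}
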
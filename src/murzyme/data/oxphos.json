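{
  "system": "oxphos",
  "description": "Mitochondrial oxidative phosphorylation: chemiosmotic rotary-synthesis model vs murburn DRS-assisted ATP synthesis.",
  "source": "no numeric indices printed for this system; classical encoded with two dozen half-events (dozens of serial binding steps) so the qualitative ordering holds; synthetic encoding",
  "classical": {
    "name": "oxphos chemiosmotic (ETC-CRAS)",
    "shape_change": 1,
    "serial": 1,
    "n_steps": 24,
    "irreducible_complexity": 1,
    "molecularity": 10,
    "long_range_et": 1,
    "es_complex": 1,
    "scheme": {"n_events": 24, "selection_factors": [], "parallel_modes": 1}
  },
  "murburn": {
    "name": "oxphos murburn",
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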
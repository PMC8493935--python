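{
  "comment": "Fixed constants of the steering-dynamics model, loaded as configuration. Magnitudes follow the original Fajen-Warren route-selection formulation (angles in radians, distances in meters).",
  "c1": 0.4,
  "c2": 0.4,
  "c3": 6.5,
  "c4": 0.8,
  "beta": 3.25,
  "gamma": 7.5,
  "epsilon": 198.0
}
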
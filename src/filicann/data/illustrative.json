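{
  "y": 23.5,
  "b": 0.04,
  "tau_a": 5.0,
  "tau_b": 80.0,
  "tau_s": 30.0,
  "k3": 1.0,
  "k4": 0.8,
  "k5": 0.55,
  "a3": 2.0,
  "a4": 6.0,
  "a5": 11.0,
  "unit_days": 5,
  "activity_minutes_per_unit": 4800,
  "egg_units": 2,
  "nymph_stage_units": 1,
  "maternal_reproductive_units": 7,
  "migration_units": 1,
  "season_units": 50
}
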
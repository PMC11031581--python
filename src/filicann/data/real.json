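{
  "y": 16.8,
  "b": 0.44,
  "tau_a": 23.3,
  "tau_b": 16.6,
  "tau_s": 5.3,
  "k3": 1.0,
  "k4": 0.8,
  "k5": 0.55,
  "a3": 0.91,
  "a4": 3.0,
  "a5": 6.14,
  "unit_days": 5,
  "activity_minutes_per_unit": 4800,
  "egg_units": 2,
  "nymph_stage_units": 1,
  "maternal_reproductive_units": 7,
  "migration_units": 1,
  "season_units": 50
}
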
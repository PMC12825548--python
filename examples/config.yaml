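# Example configuration for `pvsignal run --config examples/config.yaml --out out/`
# Omitted synthetic fields fall back to the study-conditions defaults
# (see pvsignal.synthetic.SyntheticConfig).
synthetic:
  n_reports: 20000
  seed: 1
  dup_rate: 0.023
  # signal_multipliers are written drug -> PT -> lambda; uncomment to override
  # signal_multipliers:
  #   clopidogrel:
  #     "Subdural hematoma": 27.0

analysis:
  study_drugs: [aspirin, clopidogrel, ticagrelor, prasugrel]
  positive_control: warfarin
  negative_control: rosuvastatin
  counting_unit: case
  # target_pt_set defaults to the CNS-hematoma preferred terms in both
  # English spellings; list them here to override.
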
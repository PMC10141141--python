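{
  "schema_version": "int",
  "status": "str",
  "seed": "int",
  "control_group": "str",
  "disease_group": "str",
  "treatment_arms": "list",
  "thresholds": {
    "alpha": "float",
    "lfc": "float",
    "recovery_bins": "list",
    "recovery_eps": "float",
    "min_dpsi": "float",
    "min_reads": "int",
    "splice_alpha": "float",
    "min_move": "float",
    "min_mean_count": "float"
  },
  "dge": {
    "n_disease_related": "int",
    "arms": "dict"
  },
  "recovery": "dict",
  "hard_targets": "dict?",
  "splicing": {
    "n_events": "int",
    "n_pass_filter": "int",
    "arms": "dict"
  }
}
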
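# Default calibration of the synthetic CTR validation study.
#
# The population emulates a 160-case chest-radiograph sample: four pathology
# strata of 40 cases and a CTR distribution with mean 0.522 and SD 0.095
# (truncated to keep thorax geometry feasible).  Observer noise is calibrated
# so that the expert annotators reproduce intra-observer ICCs near 0.98 and
# an inter-observer ICC near 0.97, and the automatic model lands in the same
# agreement range with a small positive bias; measurement noise is inflated
# in the effusion and consolidation strata, where fluid or airspace opacity
# obscures the cardiac and thoracic borders.
population:
  n_per_category: 40
  ctr_mean: 0.522
  ctr_sd: 0.095
  ctr_bounds: [0.2, 0.9]
  difficulty_log_sd: 0.25 # heavy-tailed per-case difficulty (unit mean square)
observers:
  experts:
    n_observers: 2
    n_sessions: 2
    bias_mean: 0.0
    bias_offsets: [-0.009, 0.009]  # fixed between-radiologist calibration offsets
    session_sd: 0.0
    within_sd: 0.012    # per-measurement noise (includes session-to-session variation)
    category_multipliers:
      normal: 1.0
      pneumothorax: 1.0
      effusion: 1.3
      consolidation: 1.3
  readers:
    n_observers: 5
    n_sessions: 1
    bias_mean: 0.0
    bias_offsets: [-0.008, -0.004, 0.0, 0.004, 0.008]
    session_sd: 0.0
    within_sd: 0.012
    category_multipliers:
      normal: 1.0
      pneumothorax: 1.0
      effusion: 1.3
      consolidation: 1.3
  model:
    n_observers: 1
    n_sessions: 1
    bias_mean: 0.0074   # small systematic overestimate by the automatic reader
    bias_offsets: [0.0]
    session_sd: 0.0
    within_sd: 0.0085
    category_multipliers:
      normal: 1.0
      pneumothorax: 1.0
      effusion: 2.0
      consolidation: 2.0
analysis:
  cutoffs: [0.50, 0.55]
  reference_modes: [dawid-skene, median]
  margin: 0.10
  n_boot_icc: 1000
  n_boot_noninferiority: 2000
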
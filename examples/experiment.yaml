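# Experiment config schema for `hapsim run --config experiment.yaml`.
# Blocks override the named parameter-set defaults; sweep_param may be a
# bare field name (if unique across blocks) or qualified as block.field.
name: class2-activation-sweep
seed: 1
network: tumor            # "tumor" | "normal" | path to a network file
network_options:          # forwarded to the network generator
  box: [300.0, 250.0, 100.0]
  n_vessels: 5
oxygen: {}                # OxygenParameters overrides (P50, M0, Km_O2, ...)
prodrug:                  # ProdrugParameters overrides
  KO2: 0.126
effector:                 # EffectorParameters overrides
  ktE: 0.01
radiation: {}             # RadiationParameters overrides (dose, OER_alpha, ...)
potency:                  # PotencyModel: case 1 scales a with kmetE
  case: 1
  a_ref: 0.200
  kmetE_ref: 0.01
sweep_param: kmetP_max
sweep_values: [0.001, 0.01, 0.1, 1.0]
include_normal: true      # paired normal-tissue run for selectivity
normal_options:
  network_options:
    box: [300.0, 250.0, 100.0]
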
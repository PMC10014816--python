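# Example model configuration: three regions, R1 -> {R2, R3} with a
# feedback connection R2 -> R1 whose strength is modulated by input u2.
# Region and input indices are 1-based. `params.defaults` is the shipped
# default physiological table (rates in 1/s, times in s); override any
# entry globally here or per region under `params.per_region`.
regions: 3
edges:
- from: 1
  to: 2
  a0: 0.4
- from: 1
  to: 3
  a0: 0.4
- from: 2
  to: 1
  a0: 0.2
modulatory_edges:
- from: 2
  to: 1
  input: 1
  b: 0.75
  modulation_only: false
driving:
- region: 1
  input: 1
  c: 0.1
params:
  defaults:
    sigma: 0.5
    mu: 0.4
    lambda_: 0.2
    sigma_tilde: 0.0
    mu_tilde: 0.0
    lambda_tilde: 0.0
    phi_decay: 0.6
    phi_gain: 1.5
    chi: 0.6
    t_mtt: 2.0
    tau: 4.0
    alpha: 0.32
    e0: 0.4
    v0: 0.04
    eps: 0.4
    theta0: 40.3
    r0: 25.0
    te: 0.035
stimuli:
  dt: 0.03125
  duration: 60.0
  n_driving: 1
  n_modulatory: 1
  n_mu: 0
  n_lambda: 0
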
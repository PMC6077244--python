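# Single-breath maneuver of a healthy non-smoker at 121 ml/s with fitted
# subject parameters; run with:
#   tmad simulate --config examples/reference_subject.yaml --out-dir out/
exchange:
  J_aw: 220.0        # maximum airway CO flux, pl/s
  D_aw: 1.6          # airway diffusing capacity, pl s^-1 ppb^-1
  J_A: 1.76e7        # maximum alveolar CO flux, pl/s
  D_A: 7400.0        # alveolar diffusing capacity, pl s^-1 ppb^-1
maneuver:
  IFR: 121.0         # inhalation flow rate, ml/s
  EFR: 121.0         # exhalation flow rate, ml/s
  V_in: 726.0        # inhaled volume, ml
  V_ex: 726.0        # exhaled volume, ml
  t_hold: 0.0        # breath-hold, s
  C_ambient: 130.0   # inhaled ambient CO, ppb
numerics:
  dz: 0.1            # grid spacing, cm
  dt: 0.01           # time step, s
sensor:
  sampling_interval_s: 0.14
  noise_sd_ppb: 2.0
seed: 1
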
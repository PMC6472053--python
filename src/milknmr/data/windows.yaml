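# Default integration windows for the ten quantification integrals.
#
# Bounds are package conventions chosen to isolate each signal from its
# neighbours; they are overridable from a run config. The C window upper
# bound (2.40) is set so that the D and C windows truncate their Lorentzian
# tails by matching fractions, keeping the UFA ratio unbiased (methods note).
# I0.95 deliberately covers both the butyric CH3 (0.95) and the
# alpha-linolenic CH3 (0.98).
windows:
  - {name: "I0.88", lo_ppm: 0.84, hi_ppm: 0.92}
  - {name: "I0.95", lo_ppm: 0.92, hi_ppm: 1.01}
  - {name: "I2.02", lo_ppm: 1.93, hi_ppm: 2.09}   # D, allylic
  - {name: "I2.33", lo_ppm: 2.25, hi_ppm: 2.40}   # C, alpha-carbonyl
  - {name: "I2.77", lo_ppm: 2.73, hi_ppm: 2.79}
  - {name: "I2.81", lo_ppm: 2.79, hi_ppm: 2.85}
  - {name: "I4.99", lo_ppm: 4.95, hi_ppm: 5.04}
  - {name: "I5.80", lo_ppm: 5.75, hi_ppm: 5.86}
  - {name: "I5.99", lo_ppm: 5.95, hi_ppm: 6.05}
  - {name: "I6.28", lo_ppm: 6.22, hi_ppm: 6.33}
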
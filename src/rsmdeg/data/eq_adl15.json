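{
 "k": 4,
 "coefficients": {
  "Intercept": 30.73,
  "A": -1.18,
  "B": 2.01,
  "C": -3.11,
  "D": -6.59,
  "A^2": -2.92,
  "B^2": -7.47,
  "C^2": -7.36,
  "D^2": -2.76,
  "AB": 0.86,
  "AC": 1.01,
  "AD": -0.16,
  "BC": 1.34,
  "BD": -4.29,
  "CD": 0.72
 }
}
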
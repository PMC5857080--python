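{
 "k": 4,
 "coefficients": {
  "Intercept": 88.76,
  "A": -6.07,
  "B": 8.01,
  "C": -0.53,
  "D": -15.95,
  "A^2": -8.7,
  "B^2": -19.74,
  "C^2": -19.4,
  "D^2": -7.18,
  "AB": 4.12,
  "AC": 1.95,
  "AD": 3.88,
  "BC": 4.14,
  "BD": -10.0,
  "CD": -4.62
 }
}
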
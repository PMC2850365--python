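{
 "f_mean_ref": 2.2e-11,
 "duration_s": 200.0,
 "n_realizations": 32,
 "seed": 20260927,
 "band_hz": [
  0.02,
  200.0
 ],
 "x": [
  1.0,
  1.1,
  1.2,
  1.3,
  1.4,
  1.5,
  1.6,
  1.7,
  1.8,
  1.9,
  2.0,
  2.1,
  2.2,
  2.3,
  2.4
 ],
 "gamma": [
  1.8571,
  1.8178,
  1.7312,
  1.649,
  1.5652,
  1.4816,
  1.3797,
  1.2767,
  1.1867,
  1.0521,
  1.0346,
  0.8229,
  0.7302,
  0.5969,
  0.5697
 ],
 "log10_amplitude": [
  -21.935,
  -21.8472,
  -21.8522,
  -21.7753,
  -21.7245,
  -21.6855,
  -21.8072,
  -22.0224,
  -22.3576,
  -22.7097,
  -22.9171,
  -23.5022,
  -23.8589,
  -24.2679,
  -24.4732
 ]
}
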
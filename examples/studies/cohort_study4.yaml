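# Classification by clinic type, independent of diagnosis
n_per_class:
  Urology: 56
  Healthy: 56
  Nephrology: 56
  Surine: 2
scans_per_specimen: 10
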
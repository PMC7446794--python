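# Urology arm + healthy-volunteer arm (healthy specimens are BCA-negative)
n_per_class:
  BCA-positive: 17
  BCA-negative: 95
  Surine: 2
scans_per_specimen: 10
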
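# Urology arm re-sorted by disease type (+9 healthy volunteers)
n_per_class:
  GU-Cancer: 25
  Other-GU-Disease: 24
  Healthy: 16
  Surine: 2
scans_per_specimen: 10
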
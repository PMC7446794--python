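# Study 5: disease-type classification among urology-clinic patients,
# one-vs-rest (rerun with each class as positive_class)
spectra: cohort5/spectra.csv
metadata: cohort5/metadata.csv
positive_class: GU-Cancer
control_classes: [Surine]
n_pcs: 10
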
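# Study 4: clinic-type classification, one-vs-rest (rerun with each class
# as positive_class to get all three metric sets)
spectra: cohort4/spectra.csv
metadata: cohort4/metadata.csv
positive_class: Urology
control_classes: [Surine]
n_pcs: 28
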
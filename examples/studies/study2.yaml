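# Study 2: healthy volunteers added as extra BCA-negative specimens
spectra: cohort2/spectra.csv
metadata: cohort2/metadata.csv
positive_class: BCA-positive
control_classes: [Surine]
n_pcs: 19
sweep: {min: 2, max: 30}
tpd: {reference: SURINE-001}
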
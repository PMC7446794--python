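# Study 3: ESKD specimens added; screen must still call them BCA-negative
spectra: cohort3/spectra.csv
metadata: cohort3/metadata.csv
positive_class: BCA-positive
control_classes: [Surine]
n_pcs: 30
tpd: {reference: SURINE-001}
contributions: {space: dapc, n_components: 4, threshold: 0.3}
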
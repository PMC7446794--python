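# Study 1: BCA-positive vs BCA-negative within the urology-clinic arm
spectra: cohort1/spectra.csv
metadata: cohort1/metadata.csv
positive_class: BCA-positive
control_classes: [Surine]
n_pcs: 10
sweep: {min: 2, max: 20}
tpd: {reference: SURINE-001, variant: abs_sum}
contributions: {space: dapc, n_components: 4, threshold: 0.3}
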
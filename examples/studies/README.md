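# Study configurations

Five ready-made `run-study` configurations mirroring the classification
schemes of a staged urine-screening programme, each running over a
synthetic cohort. Generate the cohort first, then run a study:

```bash
ramscreen simulate --config examples/studies/cohort_study1.yaml --seed 1 --out cohort1/
ramscreen run-study --config examples/studies/study1.yaml --out study1_out/
```

- **study1** — urology-clinic arm only: BCA-positive vs BCA-negative, with
  the Surine control fitted as its own class but excluded from the counts.
- **study2** — adds a healthy-volunteer arm as extra BCA-negative specimens.
- **study3** — further adds a nephrology-clinic (ESKD) arm; the screen must
  keep calling kidney-disease urine BCA-negative.
- **study4** — classifies by clinic type (urology / healthy / nephrology),
  evaluated one-vs-rest via `positive_class`.
- **study5** — urology arm re-labelled as GU-Cancer / Other-GU-Disease /
  Healthy, one-vs-rest.

Each config documents its cohort composition inline; edit `spectra` /
`metadata` paths if your cohort lives elsewhere.
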
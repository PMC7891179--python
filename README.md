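# oculomet

Oculomotor feature extraction and diagnostic classification for clinical
video-oculography batteries.

Eye movements are driven by a widespread cortical network, and different
dementias damage different parts of it: Alzheimer's disease (AD)
predominantly harms posterior parietal/temporal regions that support
visually-guided saccades and smooth pursuit, while behavioral-variant
frontotemporal dementia (bvFTD) harms frontal regions that support
volitional saccades (antisaccades, memory-guided saccades).  A standardized
eye-tracking battery therefore yields a parameter profile — latencies,
endpoint errors, pursuit gain and error, success percentages — that can
separate AD, bvFTD, semantic-variant primary progressive aphasia (svPPA)
and cognitively unimpaired controls.

`oculomet` implements that analysis end to end for researchers working with
(or prototyping against) such batteries:

- **`protocol_io`** — data model for gaze recordings (CSV + JSON sidecar),
  seeded test protocols (12 horizontal + 8 vertical trials per saccadic
  test at ±5/±10/±20° H and ±5/±12° V; 6 + 6 sinusoidal pursuit trials),
  and a packaged fixture of published group parameter distributions.
- **`synthetic_gaze`** — a generative model of the battery: per-subject
  latent parameters drawn from group (mean, SD) marginals as truncated
  normals, trials synthesized with main-sequence saccade kinematics
  (duration `d0 + k·A`), Gaussian positional noise and blink spans, with a
  per-trial ground-truth record for validating the extractor.
- **`oculometrics`** — saccade detection (velocity threshold on a
  Savitzky–Golay smoothed derivative, template-refined onsets), latency /
  signed endpoint error / antisaccade and memory-saccade outcome scoring /
  pursuit gain and error, aggregated to one feature vector per subject.
- **`group_stats`** — ANOVA with Tukey post hoc (crude p), general linear
  models with age and sex covariates (adjusted p), the Spearman p < 0.1
  sedative screen, group contrasts and neuropsychology correlation panels.
- **`classifier`** — z-normalization `x̂ = (x − x̄)/σ` with stored training
  statistics, univariate P < 0.001 feature selection, Fisher discriminant
  ratio ranking `FDR = (μ₁ − μ₂)²/(σ₁² + σ₂²)`, NIPALS PLS2
  (`X = TPᵀ + E`, `Y = UQᵀ + F`), an SVM/KNN model search by
  cross-validated AUC, a 1,000-iteration stratified 80/20 confidence loop
  (best/worst/mean AUC and accuracy), and external-cohort validation
  without refitting.
- **`pipeline` / `cli`** — config-driven `simulate → extract → stats →
  classify` runs with provenance, plus thin `oculomet` subcommands
  (`simulate`, `extract`, `stats`, `classify`, `run`, `report`).

## Worked example

`examples/03_classification_loop.py` samples an idealized AD-vs-control
cohort (18 + 29 subjects) from the packaged group distributions, selects
features at P < 0.001, ranks them by FDR and runs the confidence loop:

```
$ python examples/03_classification_loop.py
selected model: svm_linear
features entering the classifier (22):
  memory_pct_correct
  anti_neg_error_h
  anti_pct_successful
  ...
mean AUC 1.0000  (best 1.0000, worst 1.0000) over 1000 iterations
mean accuracy 1.0000  (best 1.0000, worst 1.0000)
```

The mean AUC is the probability that a random AD-like subject scores more
"AD-like" than a random control across re-randomized 80/20 splits; because
the synthetic features are sampled independently (no covariance is
published), separability is an upper bound on what correlated clinical
data would give.  `examples/01_simulate_and_extract.py` exercises the full
trace-level path instead (extracted parameters printed next to generator
truth), `02` the statistics table, `04` external validation on a milder
shifted cohort.

A full config-driven run:

```bash
oculomet run --config examples/run_config.yaml --out runs/demo
oculomet report --run-dir runs/demo
```

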
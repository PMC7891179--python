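# Full pipeline run: simulate -> extract -> stats -> classify.
# Group sizes follow the published discovery cohort.
seed: 7
sizes:
  control: 29
  AD: 18
  bvFTD: 18
  svPPA: 7
write_traces: false
classify:
  enabled: true
  pairs: ["AD:control", "bvFTD:control", "AD:bvFTD"]
  model: auto          # search SVM (linear/RBF) and KNN (k in 1,3,5,7)
  iterations: 1000
  selection: split     # leakage-guarded; "cohort" fixes features before the loop
  p_threshold: 0.001
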
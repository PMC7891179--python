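"""Reproduce the univariate group-comparison table on a synthetic cohort.

Simulates a small four-group cohort, extracts features, then runs the
ANOVA/Tukey + covariate-adjusted GLM battery (with the sedative Spearman
screen) for two headline parameters and prints the resulting p-values and
the AD-control contrast.
"""

import numpy as np
import pandas as pd

from oculomet import DetectionParams, generate_cohort, load_group_profiles
from oculomet.group_stats import group_contrast, parameter_table
from oculomet.oculometrics import aggregate_subject, analyze_trial

profiles = load_group_profiles()
records, _ = generate_cohort(profiles, (20, 14, 14, 6), seed=11)
det = DetectionParams()
rows = []
for rec in records:
    row = {"subject": rec.subject_id, "group": rec.group, "age": rec.age,
           "sex": rec.sex, "sedatives": rec.sedatives}
    row.update(aggregate_subject(
        [analyze_trial(tr, det) for ts in rec.recordings.values() for tr in ts]
    ))
    rows.append(row)
features = pd.DataFrame(rows)

table = parameter_table(features, ["pursuit_error_h", "anti_pct_successful"])
for name, res in table.items():
    print(f"\n{name}: group-effect P = {res.group_p:.2e} (F = {res.f_stat:.1f})")
    for pair in (("AD", "control"), ("AD", "bvFTD")):
        crude = res.pair_p(*pair)
        adj = res.pair_p(*pair, adjusted=True)
        print(f"  {pair[0]:>6s} vs {pair[1]:<8s} crude P {crude:.4g}  adjusted P {adj:.4g}")
    print(f"  covariates used: {res.covariates}")

diff = group_contrast(features, "pursuit_error_h", "AD", "control")
print(f"\nAD - control horizontal pursuit error on this cohort: {diff:.2f} deg")
print(f"(published tables give {group_contrast(profiles, 'pursuit_error_h', 'AD', 'control'):.2f} deg)")
print(
    "\nPursuit error separates the Alzheimer-like group; the adjusted"
    "\np-values control for age, sex and, where the screen fires, sedatives."
    "\nTrace-level cohorts realize somewhat larger pursuit errors than the"
    "\nprinted means because a subject's positional error can never fall"
    "\nbelow the floor implied by their own pursuit gain."
)
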
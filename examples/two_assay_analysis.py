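"""Two-assay accuracy analysis on a synthetic case/control study.

Emulates a study in which every subject has a clinical assay W (unbiased,
error SD 1) and a research assay M that is linearly related to the true
biomarker (M = 0.2 + 0.8 X + V).  The workflow calibrates M against W
through the disease indicator, identifies all error variances from the
pair, and reports naive, correction-for-attenuation, and skew-normal
corrected estimates of AUC/sensitivity/specificity with bootstrap SEs.
"""

import dataclasses

from snroc import BootstrapSpec, PRESETS, StudyTable, analyze, generate, truth

scenario = dataclasses.replace(PRESETS["T5"], family="skew_normal", seed=11)
data = generate(scenario, seed=11)
table = StudyTable(
    subject_id=data.index.astype(str).to_numpy(),
    y=data["Y"].to_numpy(),
    w=data["W"].to_numpy(),
    m=data["M"].to_numpy(),
)

report = analyze(
    table,
    model="linear_m",
    cutoff_rule="min_distance",
    boot=BootstrapSpec(n_boot=200, seed=11),
)
tr = truth(scenario)
print(report.round(4).to_string(index=False))
print(f"\npopulation truth: AUC={tr.auc:.3f}, Se={tr.se:.3f}, Sp={tr.sp:.3f}")
print(
    "\nThe naive row uses the biased research assay directly and understates "
    "the AUC; the corrected rows recover values near the truth, with the "
    "composite (WM) and skew-normal estimators trading off efficiency and "
    "robustness to the skewed biomarker distribution."
)
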
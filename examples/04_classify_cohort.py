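"""Nested cross-validated random-forest classification on a small cohort.

A 10-patient phantom cohort is segmented, labelled from the voxel ground
truth and classified with the patient-level nested scheme (3 rotating parts,
hyperparameter selection on the validation part).  A small forest and two
repetitions keep this demo quick; the full evaluation uses 60 patients,
10 repetitions and 300 trees.
"""

import warnings

from petlymph import CVConfig, PipelineConfig, generate_cohort, run_pipeline

cfg = PipelineConfig(seed=5, cv=CVConfig(repetitions=2, n_trees=80,
                                         depth_grid=(8, None), mtry_grid=(6,),
                                         seed=5))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cohort = generate_cohort(10, seed=5)
    result = run_pipeline(cohort, cfg)

print(result.report.text_table())
b = result.report.to_dict()["binary"]
print(f"\ntumor/non-tumor: sensitivity {b['sensitivity']}%, "
      f"specificity {b['specificity']}%, PPV {b['ppv']}%, NPV {b['npv']}%")
print("Rows are the automatic class, columns the (ground-truth) manual class;"
      " T and T+NT volumes count as tumor.")
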
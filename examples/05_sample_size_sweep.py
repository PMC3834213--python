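"""Classifier accuracy as a function of cohort size.

Draws balanced sub-cohorts (half patients, half controls) of
increasing size from a synthetic cohort and runs LOOCV on each,
showing how quickly each classifier's accuracy stabilizes with sample
size.
"""

from elmcortex import (CohortSpec, PipelineConfig, generate_cohort,
                       run_sample_size_sweep)

spec = CohortSpec(n_patients=30, n_controls=30, seed=2)
table = generate_cohort(spec)
config = PipelineConfig(seed=11, classifiers=("elm",))

df, report = run_sample_size_sweep(table, config, spec.informative_indices,
                                   sizes=(10, 20, 30, 40, 50, 60))
print(report)
# Training accuracy falls and testing accuracy rises toward their
# asymptotes as the cohort grows; the gap between them measures
# overfitting at each size.
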
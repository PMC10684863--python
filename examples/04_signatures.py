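"""Global-median signatures: which phenotypes dominate at which ages.

Each cell is the percentage of an age group's subjects whose phenotype
frequency exceeds the cohort-wide median; values above 50% (marked *)
flag age groups where the phenotype is over-represented.  The equalized
heatmap rescales each phenotype across groups to [0, 1] to expose the
rhythm independent of its amplitude.
"""
from immunorhythm import (equalize_heatmap, generate_cohort,
                          study_params, signature_proportions)

cohort = generate_cohort(study_params(), seed=1)
sig = signature_proportions(cohort)

annotated = sig.values.round(0).astype(int).astype(str)
annotated = annotated.where(~sig.highlight, annotated + "*")
print("% of subjects above the global median (* = above 50%):")
print(annotated.T)

heat = equalize_heatmap(sig)
print("\nequalized heatmap values (min-max per phenotype across groups):")
print(heat.values.round(2).T)
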
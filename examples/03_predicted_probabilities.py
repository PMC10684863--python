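"""Logistic predicted-probability curves along the age continuum.

Each phenotype is dichotomized at the 75th percentile of its empirical
distribution ('high' frequency), then the probability of being high is
modelled as a logistic function of age in months.  A negative slope
means the phenotype becomes less prevalent with age (naive subsets), a
positive slope the opposite (memory subsets).  Hosmer-Lemeshow p > 0.05
indicates adequate calibration.
"""
from immunorhythm import fit_stratum, generate_cohort, study_params
from immunorhythm.probability import probability_curves

cohort = generate_cohort(study_params(), seed=1)
fits = fit_stratum(cohort, "ALL")
cols = ["phenotype", "cutoff", "beta1", "p_slope", "hl_p"]
print(fits[cols].round(4).to_string(index=False))

curves = probability_curves(fits, age_grid=[12, 60, 120, 210])
wide = curves.pivot(index="phenotype", columns="age_months",
                    values="probability").round(2)
print("\npredicted probability of 'high' frequency at selected ages (months):")
print(wide)
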
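"""Generate a synthetic resting-state cohort and summarize its demographics.

The generator emulates an aging-cohort study: two sex groups with
Table-1-like covariates (age, education, handedness, APOE4), one to three
fMRI sessions per subject, amyloid-PET SUVR values straddling the 1.11
positivity cutoff, and sex-specific between-region covariance for the
regional time series.
"""

import fctopo
from fctopo.inference import classify_amyloid, demographics_table

config = fctopo.SimConfig(n_men=48, n_women=74, n_regions=20, n_timepoints=100,
                          seed=7)
cohort = fctopo.generate_cohort(config)

print(f"subjects: {len(cohort.subjects)}  sessions: {len(cohort.sessions)}")
print(f"sessions per subject: "
      f"{len(cohort.sessions) / len(cohort.subjects):.2f} (target ~1.65)\n")

# chi-square rows compare subject counts, t rows compare session-level means
print(demographics_table(cohort.subjects, cohort.sessions).to_string(index=False))

status = classify_amyloid(cohort.sessions)
print("\namyloid status per session (SUVR > 1.11 within 1 year of MRI):")
print(status.value_counts().to_string())
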
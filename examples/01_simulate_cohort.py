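"""Generate a synthetic elderly screening cohort and inspect its structure.

Draws n = 3014 subjects aged >= 65 with realistic risk-factor prevalences,
labs consistent with guideline phenotyping, per-subject ECG episode lists,
and AF outcomes calibrated to 22.6 % overall / 9.3 % silent prevalence.
"""

import json

import numpy as np

from mrdash import CohortSpec, generate_cohort, phenotype_cohort, cohort_to_frame

spec = CohortSpec(n_subjects=3014, seed=1)
subjects = generate_cohort(spec)
phenotyped, excluded = phenotype_cohort(subjects)
frame = cohort_to_frame(phenotyped)

print(f"subjects: {len(frame)} (excluded for missing labs: {len(excluded)})")
print(f"age: mean {frame['age'].mean():.1f}, SD {frame['age'].std():.1f}, "
      f"min {frame['age'].min():.1f}")
print(f"male: {100 * (frame['sex'] == 'male').mean():.1f}%")
print(f"AF overall:    {100 * (frame['af_status'] != 'no_af').mean():.1f}%")
print(f"silent AF:     {100 * (frame['af_status'] == 'silent_af').mean():.1f}%")
print(f"symptomatic:   {100 * (frame['af_status'] == 'symptomatic_af').mean():.1f}%")
med_days = np.median(frame["effective_monitoring_s"]) / 86400
print(f"median effective monitoring: {med_days:.1f} days")
n_episodes = frame["episodes"].map(lambda e: len(json.loads(e))).sum()
print(f"total confirmed ECG episodes: {n_episodes}")
print("\nEvery AF-positive subject carries at least one episode > 30 s; the")
print("episode filter, not the latent label, decides AF status downstream.")
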
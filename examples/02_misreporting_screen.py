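"""Flag implausible energy reporters with the EI:BMR tail screen.

Estimates each participant's basal metabolic rate from the weight-only
Schofield equations, forms the ratio of reported energy intake to BMR, and
trims the top and bottom 2.5% of the ratio distribution (floor(0.025*N) per
tail) — the distributional simplification of the Goldberg cut-off.
"""

import numpy as np

from dqscore import ParticipantProfile, schofield_bmr, screen_cohort

rng = np.random.default_rng(0)

profiles = []
energy = {}
for i in range(80):
    pid = f"p{i:03d}"
    sex = "woman" if i % 3 else "man"
    age = float(rng.uniform(18, 65))
    weight = float(rng.normal(95 if sex == "woman" else 108, 14))
    profiles.append(ParticipantProfile(pid, sex, age, weight))
    bmr = schofield_bmr(sex, age, weight)
    # plausible reporters cluster near EI:BMR ~ 0.9; plant two extremes
    energy[pid] = 1000 * bmr * float(rng.normal(0.9, 0.15))
energy["p000"] = 1000.0    # implausibly low reporter
energy["p001"] = 30000.0   # implausibly high reporter

results = screen_cohort(energy, profiles)
excluded = [r for r in results if r.excluded]
print(f"screened {len(results)} participants; excluded {len(excluded)} "
      f"(floor(0.025*{len(results)}) = {len(results)//40} per tail)")
for r in excluded:
    print(f"  {r.participant_id}: EI:BMR = {r.ei_bmr_ratio:.2f} "
          f"(BMR {r.bmr_mj_per_day:.2f} MJ/day) -> {r.reason}")
print("Excluded participants are removed before any scoring-based analysis;")
print("everyone else proceeds to DQS scoring.")
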
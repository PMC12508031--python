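"""Generate a synthetic task-fMRI cohort and inspect its structure.

Builds a 100-subject toy cohort (48 vertices per hemisphere, 17 task
epochs, 12 networks) with planted leftward language lateralization and
contralateral motor asymmetry, then prints the covariate table head and
the planted-versus-realized laterality for the language network.
"""

import numpy as np

import hemiasym as ha

cfg = ha.CohortConfig(n_subjects=100, n_vertices=48, seed=7)
cohort = ha.generate_cohort(cfg)

print(cohort.subjects.head()[["subject_id", "age", "sex", "bmi", "accuracy_story"]])
print(f"\nmap array shape (subjects, epochs, vertices): {cohort.left.shape}")
print(f"accuracy clipping fraction: {cohort.accuracy_clip_fraction:.4f}")

lan = cohort.partition == "LAN"
j = cohort.epochs.index("story")
realized = cohort.asymmetry()[:, j, :][:, lan].mean()
planted = cfg.delta_planted.loc["LAN", "story"]
print(f"\nLAN story asymmetry: planted Δ = {planted:.3f}, cohort mean = {realized:.3f}")
print("The realized laterality index tracks the planted value; residual",
      "deviation comes from vertex noise and the amplitude-asymmetry coupling.")
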
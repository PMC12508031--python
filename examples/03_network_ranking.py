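"""Aggregate asymmetry maps into network-epoch matrices and rank them.

Networks are ranked by the root-mean-square of their cohort-mean
asymmetry across epochs (magnitude regardless of direction); epochs by
the signed mean across networks (net leftward vs rightward bias).  The
motor contrast subtracts the average of the five movement epochs from
each, isolating movement-specific lateralization.
"""

import hemiasym as ha

cohort = ha.generate_cohort(ha.CohortConfig(n_subjects=120, n_vertices=48, seed=5))
nem = ha.aggregate_cohort_arrays(
    cohort.asymmetry(), cohort.partition, cohort.subject_ids, cohort.epochs,
    "asymmetry",
)

print("networks ranked by RMS asymmetry:")
for k, v in ha.rank_networks(nem).items():
    print(f"  {k:5s} {v:.4f}")

print("\ntop epochs by signed mean asymmetry (positive = leftward):")
for e, v in list(ha.rank_epochs(nem).items())[:5]:
    print(f"  {e:7s} {v:+.4f}")

nem_amp = ha.aggregate_cohort_arrays(
    cohort.amplitude(), cohort.partition, cohort.subject_ids, cohort.epochs,
    "amplitude",
)
motor = ha.motor_vs_average(nem_amp)
smm = motor.values["SMM"].mean()
print("\nSMM motor-vs-average amplitude contrasts (cohort mean):")
print(smm.round(4).to_string())
print("Somatomotor and language networks lead the RMS ranking because the",
      "generator plants contralateral motor and leftward language asymmetry.")
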
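"""Compute laterality and amplitude maps for one subject and check
hemisphere correspondence.

The laterality index Δ = (L−R)/(|L|+|R|) is bounded in [−1, 1]; positive
values mean leftward lateralization.  The correspondence check verifies
that vertex v of each hemisphere is the mirrored anatomical homologue of
the other by correlating bounding-box-centered coordinates per axis.
"""

import hemiasym as ha

cohort = ha.generate_cohort(ha.CohortConfig(n_subjects=5, n_vertices=48, seed=3))
pair = cohort.pair("sub-0000", "story")

asym = ha.compute_asymmetry(pair)
amp = ha.compute_amplitude(pair)
print(f"subject {pair.subject_id}, epoch {pair.epoch}")
print(f"Δ range: [{asym.values.min():+.3f}, {asym.values.max():+.3f}], "
      f"mean {asym.values.mean():+.3f}  ({asym.n_degenerate} degenerate vertices)")
print(f"A range: [{amp.values.min():.3f}, {amp.values.max():.3f}]")

rep = ha.verify_correspondence(pair)
print(f"coordinate correlations (x, y, z): "
      f"{rep.r_x:.4f}, {rep.r_y:.4f}, {rep.r_z:.4f} -> pass={rep.passed}")
print("Correlations above 0.995 confirm mirrored vertex-wise homology, so the",
      "left-right subtraction compares anatomically corresponding locations.")
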
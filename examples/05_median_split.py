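"""Median split of per-subject composition scores into low/high groups.

Scores here are synthetic stand-ins for per-patient stroma-to-tumor ratios;
in a real cohort they come from `composition()` on each patient's classified
slide. The split at the median keeps the groups near-equal in size for
downstream survival comparison (fit with your statistics package of choice).
"""

import numpy as np

import histomap as hm

rng = np.random.default_rng(0)
scores = {f"patient_{i:02d}": float(s) for i, s in enumerate(rng.beta(2, 5, size=12))}

groups = hm.median_split(scores)
median = float(np.median(list(scores.values())))
print(f"median stroma ratio: {median:.3f} (scores <= median -> 'low')")
for patient, score in sorted(scores.items(), key=lambda kv: kv[1]):
    print(f"  {patient}  score {score:.3f}  -> {groups[patient]}")
n_low = sum(g == "low" for g in groups.values())
print(f"group sizes: low {n_low}, high {len(groups) - n_low}")
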
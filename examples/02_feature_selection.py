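"""Correlation-driven descriptor selection and (0,1) scaling.

Zero-variance descriptors are dropped, any pair with |Pearson r| > 0.8 is
reduced to its stronger target correlate, survivors are ranked by |r with
logS0| and the top 10 become the network inputs.  Scaling statistics come
from the training set only.
"""

import solqspr as sq

study = sq.generate_study(seed=1)
ds = sq.curate(study.records, study.descriptors)

sel = sq.select_top_k(ds.X, ds.y, k=10, threshold=0.8)
print("descriptor ranking (signed Pearson r with logS0):")
for name, r in sel.ranked:
    mark = "*" if name in sel.selected else " "
    print(f"  {mark} {name:6s} {r:+.3f}")

scaling = sq.fit_scaling(ds.X[sel.selected], ds.y)
scaled = scaling.transform_features(ds.X[sel.selected])
print(f"\nscaled training columns span [{scaled.min().min():.2f}, "
      f"{scaled.max().max():.2f}] (endpoints attained by construction)")

# The partition-coefficient surrogate (ALOGP) leads the ranking with a
# strongly negative correlation: more lipophilic molecules dissolve less.
# Test compounds scaled with these training min/max values may fall outside
# [0, 1]; they are deliberately not clipped.
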
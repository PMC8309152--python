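"""Assess which test compounds the training data can actually speak for.

Two diagnostics on the scaled selected descriptors: the 95% chi-square
ellipse on the first two principal components of the training cloud, and
the normalized Euclidean similarity sim(a,b) = 1 - ||a-b||/sqrt(m) used to
find each compound's 10 nearest training neighbours.
"""

import solqspr as sq
from solqspr.domain import fit_doa, similarity_matrix

study = sq.generate_study(seed=1)
ds = sq.curate(study.records, study.descriptors)
sel = sq.select_top_k(ds.X, ds.y, k=10)
scaling = sq.fit_scaling(ds.X[sel.selected], ds.y)
Xs = scaling.transform_features(ds.X[sel.selected])

model = sq.train_mlp(Xs, scaling.transform_target(ds.y), sq.MlpConfig(seed=0),
                     scaling=scaling, feature_names=sel.selected)
doa = fit_doa(Xs)
print(f"PC1+PC2 explain {100 * doa.explained_variance_ratio[:2].sum():.0f}% "
      "of the training descriptor variance")

loose = study.test_loose
report = sq.doa_report(doa, scaling.transform_features(loose[sel.selected]),
                       list(loose["compound_id"]), loose["logS0"],
                       model.predict(loose), Xs, ds.y.to_numpy(),
                       list(ds.table["compound_id"]))
inside = report["inside_95"]
print(f"loose set: {int(inside.sum())}/{len(report)} compounds inside the ellipse")

sims = similarity_matrix(scaling.transform_features(loose[sel.selected]), Xs)
worst = report.loc[(report["exp_logS0"] - report["pred_logS0"]).abs().idxmax()]
print(f"\nworst-predicted compound {worst['compound_id']}: "
      f"experimental {worst['exp_logS0']:.2f}, predicted {worst['pred_logS0']:.2f}")
print(f"  inside ellipse: {worst['inside_95']}, "
      f"max similarity to training: {worst['max_similarity']:.2f}")
print(f"  10-NN logS0: mean {worst['nn_mean']:.2f}, "
      f"range ({worst['nn_min']:.2f}, {worst['nn_max']:.2f})")

# Compounds far from every training molecule (low max similarity) or whose
# solubility disagrees with their neighbourhood are exactly where the
# network's errors concentrate — predictions there deserve extra caution.
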
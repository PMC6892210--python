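"""Score a generated molecule set the way target-biased studies are judged.

Builds a labeled target library, fits the FCFP6 SVM on a series split,
then evaluates a mock 'generated' sample: validity/uniqueness/novelty,
predicted activity, recovered held-out actives and neighbors, similarity
profiles, scaffold overlap, QED/SA, and the MQN-PCA chemical-space summary.
"""

import numpy as np

from latentgan import (
    FixtureSpec,
    generate_library,
    mqn,
    overlap_analysis,
    pca_projection,
    plant_actives,
    qed_score,
    sa_score,
    sample_report,
    series_split,
    similarity_profile,
    train_target_model,
)

spec = FixtureSpec(n_molecules=200, n_series=8, actives_fraction=0.4, seed=11)
labeled = plant_actives(generate_library(spec), spec)
split = series_split(labeled, seed=0)
model = train_target_model(labeled, split, seed=0)
print(f"SVM on held-out series: ROC-AUC {model.roc_auc:.3f}, "
      f"kappa {model.kappa:.3f}")

train_actives = [labeled[i].canonical_smiles for i in split.train_ids
                 if labeled[i].activity_label == "active"]
test_actives = [labeled[i].canonical_smiles for i in split.test_ids
                if labeled[i].activity_label == "active"]

# mock sample: some training actives, some held-out actives, some junk
rng = np.random.default_rng(0)
sample = (list(rng.choice(train_actives, 20)) + test_actives[:3]
          + ["not_a_smiles", "C(("])
report = sample_report(sample, train_actives, test_actives, model)
print(f"valid {report.valid_pct:.0f}%  unique {report.unique_pct:.0f}%  "
      f"novel {report.novel_pct:.0f}%  active {report.active_pct:.0f}%")
print(f"recovered actives {report.recovered_actives_pct:.1f}%  "
      f"neighbors(T>=0.7) {report.recovered_neighbors}")

profile = similarity_profile(test_actives, train_actives)
print("nearest-neighbor similarity bins:",
      {k: round(v, 2) for k, v in profile.bins.items()})

counts = overlap_analysis(train_actives, test_actives)
print(f"scaffold overlap train/test actives: {counts.scaffolds_shared}")

smiles = [r.canonical_smiles for r in labeled]
_, evr, _ = pca_projection(np.stack([mqn(s) for s in smiles]), k=2)
print(f"MQN-PCA explained variance (2 components): {evr.sum():.1f}%")
print(f"QED mean {np.mean([qed_score(s) for s in smiles]):.2f}, "
      f"SA mean {np.mean([sa_score(s) for s in smiles]):.2f}")
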
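"""Train and model-select both classifier families on ICA features.

Builds a patch dataset, splits it into train / validation / test, fits the
ICA basis on the training patches only, then grid-selects an Rprop MLP and
an RBF SVM by validation AUC and reports their test-set ROC AUC.
"""

import numpy as np

from mammica import (
    SyntheticConfig,
    fit_basis,
    generate_patch_dataset,
    grid_select_mlp,
    project,
    roc_curve,
    train_svm_grid,
)

cfg = SyntheticConfig(seed=2, n_images_per_density=40, mass_fraction=0.5)
patches = generate_patch_dataset(cfg, patch_side=32, n_normal_per_image=1)
y = np.array([1 if p.is_mass else 0 for p in patches])
X = np.stack([p.pixels.ravel() for p in patches])

rng = np.random.default_rng(0)
idx = rng.permutation(len(y))
tr, va, te = idx[:100], idx[100:130], idx[130:]

basis = fit_basis(X[tr], n_components=10, seed=0)
F = {s: project(X[i], basis) for s, i in (("tr", tr), ("va", va), ("te", te))}

mlp = grid_select_mlp(
    F["tr"], y[tr], F["va"], y[va],
    hidden_grid=(50, 100), restarts=2, seed=0, max_epochs=300,
)
print(f"MLP selected: {mlp.selection['n_hidden']} hidden units "
      f"(restart {mlp.selection['restart']}, val AUC {mlp.selection['val_auc']:.3f})")

svm = train_svm_grid(F["tr"], y[tr], F["va"], y[va])
print(f"SVM selected: C=2^{np.log2(svm.selection['C']):.1f}, "
      f"gamma=2^{np.log2(svm.selection['gamma']):.1f} "
      f"(val AUC {svm.selection['val_auc']:.3f})")

for name, clf in (("MLP", mlp), ("SVM", svm)):
    auc = roc_curve(clf.score(F["te"]), y[te]).auc
    print(f"{name} held-out test AUC: {auc:.3f}")
print("\nSelection uses validation data only; the test fold is scored once.")
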
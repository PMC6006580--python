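"""Five-fold cross-validation and a small hyperparameter grid.

Positives are split into five folds; each fold is masked in turn, the model
is refitted, and the held-out positives are ranked against all true zeros.
"""

from scmf import Hyperparameters, SyntheticSpec, cross_validate, generate, grid_search

data = generate(SyntheticSpec(n=60, m=60, k_true=4, richness=0.1, seed=0))

hp = Hyperparameters(k_fraction=0.45, mu=1.0, lam=4.0, seed=0,
                     max_sweeps=100, tol=1e-5)
report = cross_validate(data.A, data.Wd, data.Ws, hp, fold_count=5, seed=0)
print(report.to_frame().round(4))
print(f"\nmean AUPR {report.mean.aupr:.4f}, mean AUC {report.mean.auc:.4f}")

# a small grid over the similarity-constraint weight
base = Hyperparameters(k_fraction=0.45, mu=1.0, seed=0, max_sweeps=60, tol=1e-5)
table = grid_search(data.A, data.Wd, data.Ws,
                    k_fractions=[0.45], mus=[1.0], lams=[0.0, 1.0, 4.0],
                    fold_count=5, seed=0, hp_base=base)
print("\nlambda sweep:")
print(table[["lam", "aupr", "auc", "best"]].round(4))
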
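"""Fit the similarity-constrained factorization and rank novel candidates.

Uses a planted synthetic dataset so the script is self-contained; with real
data you would load the association matrix and similarities from files
(scmf.io.read_associations / read_similarity) instead.
"""

import numpy as np

from scmf import Hyperparameters, SyntheticSpec, fit, generate, predict

data = generate(SyntheticSpec(n=60, m=60, k_true=4, richness=0.1, seed=0))
print(f"{data.A.n_drugs} drugs x {data.A.n_diseases} diseases, "
      f"{data.A.n_associations} known associations")

hp = Hyperparameters(k_fraction=0.45, mu=1.0, lam=4.0, seed=0)
result = fit(data.A, data.Wd, data.Ws, hp)
print(f"converged={result.converged} after {result.sweeps_run} sweeps, "
      f"objective {result.objective_trace[0]:.1f} -> {result.objective_trace[-1]:.1f}")

# rank unknown cells (known associations excluded) by predicted score
scores = predict(result.factors)
known = data.A.values == 1
scores_masked = np.where(known, -np.inf, scores)
flat = np.argsort(-scores_masked, axis=None)[:5]
print("\ntop 5 novel candidates:")
for idx in flat:
    i, j = np.unravel_index(idx, scores.shape)
    print(f"  {data.A.drug_ids[i]} - {data.A.disease_ids[j]}  score {scores[i, j]:.3f}")
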
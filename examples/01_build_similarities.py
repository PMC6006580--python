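"""Build the two similarity matrices the factorization consumes.

Drug similarity is the Jaccard index of binary descriptor vectors (e.g.
substructure fingerprints); disease similarity is the MeSH semantic measure
computed on the DAGs spanned by each disease's tree numbers.
"""

import numpy as np

from scmf import BinaryFeatureTable, build_dag, pairwise_jaccard, pairwise_semantic

# --- drugs: three toy fingerprints over four substructure bits --------------
table = BinaryFeatureTable(
    entity_ids=["aspirin", "ibuprofen", "metformin"],
    descriptors=["ring", "carboxyl", "ether", "amine"],
    bits=np.array([[1, 1, 0, 0],
                   [1, 1, 1, 0],
                   [0, 0, 0, 1]]),
)
Wd = pairwise_jaccard(table)
print("drug similarity (Jaccard):")
print(np.round(Wd.values, 3))
# aspirin/ibuprofen share 2 of 3 descriptors -> 2/3; metformin shares none.

# --- diseases: MeSH tree numbers define a small DAG per disease -------------
dags = [
    build_dag(["C14.280.238"], disease_id="cardiomyopathy"),
    build_dag(["C14.280.434"], disease_id="heart failure"),
    build_dag(["C04.557.337"], disease_id="lymphoma"),
]
Ws = pairwise_semantic(dags, delta=0.5)
print("\ndisease similarity (MeSH semantic):")
print(np.round(Ws.values, 3))
# the two heart diseases share the C14 -> C14.280 ancestry and score high;
# lymphoma shares no ancestors with either and scores 0.
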
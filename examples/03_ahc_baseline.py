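"""Agglomerative clustering baseline: sensitivity to its cut threshold.

UPGMA (average-linkage) clustering needs a Euclidean distance threshold
to turn its dendrogram into a hierarchy.  The sweep below shows how
strongly the average edge error depends on that choice on planted data -
the sensitivity that motivates a model-based alternative.
"""

import numpy as np

from attrtree import threshold_sweep
from attrtree.synthetic import PlantedSpec, make_planted_model, simulate_dataset

model = make_planted_model(PlantedSpec(N=150, seed=3))
data, _, _ = simulate_dataset(model)
print(f"UPGMA on {data.n} instances x {data.D} attributes\n")
print(f"{'threshold':>10} {'avg edge error':>15}")
for t, err in threshold_sweep(data, model.taxonomy, list(np.linspace(0.5, 4.0, 8))):
    print(f"{t:>10.2f} {err:>15.3f}")
print("\nsmall thresholds over-fragment (inflated distances); large ones")
print("collapse everything into one cluster (distances all zero).")
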
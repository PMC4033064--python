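"""The average edge error metric on a worked three-instance example.

Two instances of category A share a node u; one instance of category B
sits at a child of u.  The ground-truth taxonomy separates A and B by
two edges, so the learned pairwise distances (0, 1, 1) miss the true
ones (0, 2, 2) by (0, 1, 1): the average over the three pairs is 2/3.
"""

import numpy as np

from attrtree import LearnedHierarchy, Taxonomy, average_edge_error
from attrtree.synthetic import PlantedSpec, make_planted_model, random_assignment_baseline, simulate_dataset
from attrtree.nodes import ROOT

taxonomy = Taxonomy(
    parent={"root": None, "A": "root", "B": "root"},
    category_node={"A": "A", "B": "B"},
    category_of={"i1": "A", "i2": "A", "i3": "B"},
)
learned = LearnedHierarchy(
    parent={"u": None, "v": "u"},
    node_of={"i1": "u", "i2": "u", "i3": "v"},
)
print(f"worked example: average edge error = {average_edge_error(learned, taxonomy):.4f}"
      "  (expected 2/3)")

# Calibration floor: scrambling assignments on a planted tree shows how
# much structure the metric actually measures.
model = make_planted_model(PlantedSpec(N=120, seed=1))
data, assignments, cats = simulate_dataset(model)
tax = model.taxonomy.with_categories(dict(zip(data.instance_ids, cats)))
parent = {n: (None if n == ROOT else n[:-1]) for n in model.nodes}
truth = LearnedHierarchy(parent, dict(zip(data.instance_ids, assignments)))
floor = random_assignment_baseline(truth, tax, np.random.default_rng(0), repeats=200)
print(f"true assignments score {average_edge_error(truth, tax):.3f}; "
      f"random assignments score {floor.mean():.3f} +- {floor.std():.3f}")
print("(a learned hierarchy is informative only below the random floor)")
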
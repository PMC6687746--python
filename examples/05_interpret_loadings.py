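"""Interpret a CCA mode through loadings, top edges and network summaries.

Loadings (structure coefficients) are the Pearson correlations of each
preprocessed variable with the canonical variate.  Edges are ranked and
the top tails per sign selected (top-k or a fraction such as 0.5%); the
selection is summarized per node by mean absolute loading and grouped by
resting-state network.
"""

import numpy as np

from neurocca import (
    EdgeIndex,
    NetworkLabelMap,
    attach_networks,
    devectorize_connectivity,
    fit_cca,
    fix_mode_signs,
    pca_reduce,
    select_top,
    summarize_by_node,
    variable_loadings,
)
from neurocca.dataio import DataMatrix
from neurocca.preprocess import standardize

rng = np.random.default_rng(5)

# Toy connectome: 10 regions -> 45 edges, subjects' edge values driven by a
# latent score that also drives a small behaviour battery.
regions = [f"R{i + 1}" for i in range(10)]
index = EdgeIndex(regions)
n = 150
z = rng.standard_normal(n)
edge_effect = rng.standard_normal(len(index))
brain = DataMatrix(
    np.outer(z, edge_effect) + rng.standard_normal((n, len(index))),
    [f"s{i}" for i in range(n)], index.edge_ids(),
)
behaviour = DataMatrix(
    np.outer(z, rng.standard_normal(6)) + rng.standard_normal((n, 6)),
    [f"s{i}" for i in range(n)], [f"item{j + 1}" for j in range(6)],
)

xb, yb = standardize(brain), standardize(behaviour)
pca_x, pca_y = pca_reduce(xb, 5), pca_reduce(yb, 3)
model = fit_cca(pca_x.component_scores[:, :3], pca_y.component_scores)
model, _ = fix_mode_signs(model, yb)
print(f"first canonical correlation: {model.correlations[0]:.3f}")

loadings = variable_loadings(xb, model.variates_x)
selection = select_top(loadings, mode=1, k=5)
print("\ntop 5 positive edges:")
for edge, value in selection.positive.items():
    print(f"  {edge}: {value:+.3f}")
print("top 5 negative edges:")
for edge, value in selection.negative.items():
    print(f"  {edge}: {value:+.3f}")

summary = summarize_by_node(selection, index)
labels = NetworkLabelMap(
    {r: ("default" if i < 4 else "visual" if i < 7 else "subcortex")
     for i, r in enumerate(regions)}
)
labelled, counts = attach_networks(summary, selection, index, labels)
print("\nper-node mean |loading| (top contributors):")
print(labelled.sort_values("mean_abs_loading", ascending=False).head(5))
print("\nselected-edge endpoints per network:")
print(counts.to_string())
# Endpoint counts sum to twice the number of selected edges; networks with
# many endpoints dominate the mode's connectivity signature.
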
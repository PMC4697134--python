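"""Neighbourhood graphs and the intrinsic CAR spatial prior.

Cluster sites are points, so spatial adjacency is a symmetrised k-nearest-
neighbour graph on great-circle distance.  The ICAR prior on a field u has
precision tau * Q with Q = D - A (the graph Laplacian): it penalises
squared differences between neighbouring clusters and is improper (flat in
each component's mean), so fields are constrained to sum to zero per
connected component.
"""

import numpy as np
import pandas as pd

from nutsurv import build_adjacency, icar_precision, sample_icar

rng = np.random.default_rng(0)
sites = pd.DataFrame({
    "id": [f"c{i}" for i in range(40)],
    "lon": 44 + 4 * rng.random(40),
    "lat": 2 + 4 * rng.random(40),
})

graph = build_adjacency(sites, method="knn", k=5)
print(f"{graph.n_nodes} sites, {len(graph.edges)} edges, "
      f"{graph.n_components} connected component(s)")

prec = icar_precision(graph)
print(f"rank(Q) = {prec.rank} = n - components; "
      f"max |row sum| = {abs(prec.Q.sum(axis=1)).max():.1e}")

x = rng.normal(size=40)
edge_sum = sum((x[graph.index_of(a)] - x[graph.index_of(b)]) ** 2 for a, b in graph.edges)
print(f"x'Qx = {prec.quadratic_form(x):.6f} vs edge sum {edge_sum:.6f}")

field = sample_icar(prec, tau=4.0, seed=1)
print(f"ICAR draw: sd = {field.std():.3f}, component sum = {field.sum():.2e}")
# the sum is zero by construction; tau controls the smoothness/scale
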
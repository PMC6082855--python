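"""Cell-to-cell structural variability through Ward linkage matrices.

Collapses several independent 200-bead chains ("cells"), builds the Ward
linkage matrix (cophenetic distances from Ward clustering of the
time-averaged distance map) for each, and prints the mean pairwise Pearson
correlation rho-bar.  Values far below 1 mean each cell folds into its own
distinct structure, while the two half-ensemble averages still agree.
"""

import numpy as np

import ccmpoly as cp
from ccmpoly.core import EnergyModel
from ccmpoly import geometry

N, CELLS = 200, 8
ann = cp.synth_annotation(N, 20, 0.24, seed=5)
loops = cp.synth_loops(N, 2, 40, seed=6)
model = EnergyModel(cp.CCMParameters(n_beads=N), ann, loops)

trajs = []
for cell in range(CELLS):
    pos0 = cp.init_extended(model, seed=cell)
    col = cp.run_langevin(pos0, model, 60_000, dt=0.01, friction_low=0.1,
                          seed=cell, save_every=60_000)
    trajs.append(cp.run_langevin(col.frames[-1], model, 30_000, dt=0.01,
                                 friction_low=1.0, seed=cell + 50,
                                 save_every=300))

wlms = [geometry.ward_linkage_matrix(geometry.mean_distance_map(t))
        for t in trajs]
rhos, rho_bar = geometry.wlm_similarity_population(wlms)
print(f"single-cell WLM similarity: rho-bar = {rho_bar:.2f} over "
      f"{len(rhos)} cell pairs (<< 1: strong cell-to-cell heterogeneity)")

half_a = geometry.ward_linkage_matrix(
    geometry.mean_distance_map(trajs[: CELLS // 2], mode="ensemble"))
half_b = geometry.ward_linkage_matrix(
    geometry.mean_distance_map(trajs[CELLS // 2 :], mode="ensemble"))
rho_ens = geometry.wlm_similarity(half_a, half_b)
print(f"ensemble WLM of two disjoint half-ensembles: rho = {rho_ens:.2f} "
      f"(ensemble averages agree even though single cells differ)")
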
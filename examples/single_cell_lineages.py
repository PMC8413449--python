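"""mtDNA-based lineage tracing in single cells of one line.

Simulates cells from three latent clones with clone-defining heteroplasmies
stable across differentiation stages, assigns stages from day/pseudotime,
aggregates pseudo-bulk heteroplasmy, checks cross-stage concordance and
recovers the clones by hierarchical clustering.
"""

import pandas as pd

from mitoshift import singlecell as sc
from mitoshift.simulate import SimulationParams, simulate_single_cells

clone_hf = pd.DataFrame(
    [[0.95, 0.0, 0.3], [0.0, 0.9, 0.3], [0.0, 0.0, 0.3]],
    columns=["1392T>G", "13327A>G", "2623A>G"])  # 2623 is ancestral
chf, expr, meta = simulate_single_cells(
    pd.DataFrame(columns=["position", "ref", "alt", "true_hf"]),
    n_cells=300, params=SimulationParams(seed=4), clone_hf=clone_hf,
    clone_frequencies=[0.2, 0.3, 0.5], hf_noise_sd=0.02)

meta = sc.assign_stage(meta).assign(line_id="L1")
print("cells per stage:", meta["stage"].value_counts().to_dict())

print("\npseudo-bulk HF (zeros included):")
print(sc.pseudo_bulk_hf(chf).round(3).to_string())
print("\ncarrier statistics:")
print(sc.carrier_statistics(chf).round(3).to_string())
# pseudo-bulk = carrier proportion x carrier-mean HF when non-carriers are 0

conc = sc.stage_concordance(chf, meta, min_cells_per_stage=20)
print("\ncross-stage R^2 of log2 carrier proportions:")
print(conc[["stage_a", "stage_b", "r2_log2_proportion"]].round(3)
      .to_string(index=False))

res = sc.lineage_clusters(chf, embedding="pca")
print("\nlineage clusters:", res.clusters.value_counts().to_dict())
print("top marker per cluster:")
print(res.markers.groupby("cluster").first()[["variant",
                                              "mean_hf_in_cluster"]])
# clusters correspond to the simulated clones; the ancestral variant at
# position 2623 is carried by every clone and does not separate them
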
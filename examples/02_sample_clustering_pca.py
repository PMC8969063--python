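"""Cluster grafting conditions and project them with PCA.

Each non-intact condition (treatment x time) is represented by its log2
expression ratio against intact tissue across all genes; Ward clustering
shows which treatments respond alike, PCA shows the same structure as
coordinates with per-component variance shares.
"""

from grafttx import aggregate_replicates, dendrogram_to_newick, pca, ratio_profiles, ward_cluster
from grafttx.simulate import SimConfig, generate_expression

cfg = SimConfig(n_genes=500, noise_sd=0.1, seed=7)
bundles, _ = generate_expression(cfg)
species = cfg.species[0]
cond = aggregate_replicates(*bundles[species])

ratios = ratio_profiles(cond, species, pseudocount=1.0)
profiles = ratios.data.loc[(ratios.data != 0).any(axis=1)]
labels = [f"{treatment}_{t}DAG" for treatment, t in profiles.columns]

dendro = ward_cluster(profiles.T.to_numpy(), labels)
print("Ward dendrogram (Newick, heights = within-cluster SSE increase):")
print(" ", dendrogram_to_newick(dendro))

result = pca(profiles.T.to_numpy())
print("\nPCA of the same profiles (rows = conditions):")
for label, (pc1, pc2) in zip(labels, result.scores.to_numpy()[:, :2]):
    print(f"  {label:<20} PC1={pc1:8.2f}  PC2={pc2:8.2f}")
print("variance explained:",
      ", ".join(f"PC{i + 1} {f:.1%}" for i, f in enumerate(result.variance_fractions[:3])))
print("Conditions that merge early / sit close share a transcriptome-wide response.")
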
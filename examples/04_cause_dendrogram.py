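"""Cluster causes of death by how they group symptoms.

Each cause carries its own symptom partition (the posterior mode of
s_c·).  The adjusted Rand index between two causes' partitions measures
how similarly they cluster symptoms; 1 - ARI is the dissimilarity fed
to average-linkage agglomeration.  With the cyclic generator, causes
whose group matrices are small rotations of each other sit closer in
the tree.
"""

from vatensor import ModelConfig, SimulationConfig, generate_dataset, run_chain
from vatensor.interpret import cause_dendrogram, cause_dissimilarity, \
    grouping_mode

sim = SimulationConfig(C=6, p=18, K=2, r=3, h=2, n_train=1200, n_target=10,
                       seed=9)
data, truth = generate_dataset(sim)
cfg = ModelConfig(model="ctucker", K=2, r=3, h=2, n_iter=600, n_burnin=200,
                  seed=2)
samples = run_chain(data, cfg)

mode, _ = grouping_mode(samples)
d = cause_dissimilarity(mode)
print("pairwise 1 - ARI dissimilarity between causes:")
print(d.round(2))
_, newick = cause_dendrogram(mode, list(data.cause_names))
print("\ndendrogram (Newick):")
print(newick)
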
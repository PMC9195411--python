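"""Feature construction: CpG-island filtering, 100 bp probe chaining and
cluster averaging on a small synthetic corpus.

Run:  python examples/01_preprocess_features.py
"""

import methylnet as mn

spec = mn.SyntheticSpec(n_classes=4, samples_per_class=30, n_islands=60,
                        non_island_fraction=0.2, seed=0)
manifest = mn.generate_manifest(spec)
beta, meta = mn.generate_cohort(spec)

island = mn.filter_island_probes(manifest)
clusters = mn.cluster_probes(island, max_gap=100)
kept = mn.filter_clusters(clusters, min_probes=4)
features = mn.build_features(manifest, beta)

print(f"manifest probes:        {len(manifest)}")
print(f"island probes:          {len(island)}  (non-island probes removed)")
print(f"100 bp chains:          {len(clusters)}")
print(f"clusters with >=4 CpGs: {len(kept)}")
print(f"feature matrix:         {features.beta.shape[0]} samples x "
      f"{features.beta.shape[1]} cluster features")
# Each feature is the mean beta of one CpG-island probe cluster, so values
# stay in [0, 1]; per-sample normalization means a sample's features never
# depend on which other samples were processed with it.
print(f"value range:            [{features.beta.values.min():.3f}, "
      f"{features.beta.values.max():.3f}]")
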
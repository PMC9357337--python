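"""Knockout screen + Essentiality Congruity Score on synthetic pathways.

Generates two seeded random pathways sharing a gene namespace and one
binary expression profile, screens every (active, knockout) instance, and
aggregates the binary calls into per-gene ECS values.
"""

import pathko as pk

spec = pk.SyntheticSpec(seed=1, n_genes=10, n_complexes=2, n_abstracts=2, n_samples=1)
networks = [
    pk.generate_network(pk.SyntheticSpec(**{**spec.__dict__, "seed": spec.seed + j}),
                        name=f"pathway_{j + 1}")
    for j in range(2)
]
profile = pk.generate_profiles(spec, networks[0])[0]

calls = pk.scan_pathways(networks, profile)
print(f"{len(calls)} (gene, pathway, active) knockout calls for sample {profile.sample_id}\n")

table = pk.ecs_table(calls, profile.sample_id)
print(table.to_string(index=False))

# ecs is the fraction of essentiality predictions (over actives that
# produced at least one essential call) in which the gene was essential:
# 1.0 = unanimously essential, 0.0 = never essential. c_g is the plain
# max-aggregated binary call; n_predictions counts the screened instances.
strict = pk.threshold_ecs(table, 0.5)
print(f"\ngenes with ECS > 0.5: {sorted(strict[strict == 1].index)}")
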
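"""The Wnt toy pathway: wild-type minima and the canonical knockouts.

The toy network has two ligand/receptor complexes (WNT5A/FZD7 and
WNT3A/FZD1), either of which can activate the planar-cell-polarity
signalling abstract. Three expression scenarios (FZD7/FZD1 always
expressed) show how the minimum number of lowly expressed genes the cell
must switch on — and how that minimum reacts to knockouts — defines
essentiality.
"""

import pathko as pk

ABSTRACT = "WNT_PCP_PATHWAY"

net = pk.toy_pathway()
print(f"pathway {net.name}: {len(net)} entities, {len(net.interactions)} edges")
print(f"actives A = {net.actives}\n")

for label, profile in pk.toy_profiles().items():
    expressed, lowly = pk.partition_genes(profile, net)
    wild = pk.solve(pk.build_problem(net, lowly, ABSTRACT))
    print(f"scenario {label}: expressed={sorted(expressed)} lowly={sorted(lowly)}")
    print(f"  wild-type minimum S_wild = {wild.objective_value}")
    for gene in sorted(expressed):
        sol = pk.solve(pk.build_problem(net, lowly, ABSTRACT, gene))
        verdict = "ESSENTIAL" if sol.objective_value > wild.objective_value else "not essential"
        print(f"  knockout {gene}: S = {sol.objective_value}  -> {verdict}")
    print()

# What the numbers mean: S counts lowly expressed genes that must be forced
# active to keep the abstract running. In scenario A one of the two WNT
# ligands is always needed (S_wild = 1) and no single knockout makes things
# worse. In scenario C the expressed route runs through FZD7, so its
# knockout raises S from 0 to 1: FZD7 is essential there.
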
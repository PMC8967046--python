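"""Walk-balance indices: balance beyond triangles, over cycles of all lengths.

K = tr(exp(A(S))) / tr(exp(A(|S|))) weights closed walks of every length
with factorially decaying weight; K = 1 iff the network is structurally
balanced. U = (1-K)/(1+K) rescales the lack of balance to [0, 1]. The
per-node K_i ranks genes by how exclusively they participate in balanced
walks.
"""

from genebalance import (
    ProfileModel,
    generate_profiles,
    profiles_to_similarity,
    shuffled_walk_balance,
    threshold_network,
    walk_balance,
)

model = ProfileModel(n_genes=150, n_modules=5, profile_length=400,
                     within_module_corr=0.5, between_module_corr=-0.125, seed=17)
net = threshold_network(profiles_to_similarity(generate_profiles(model)), 0.2)

wb = walk_balance(net)
sh = shuffled_walk_balance(net, M=10, seed=1)
print(f"nodes {net.n_nodes}, edges {net.n_edges}")
print(f"K original  {wb.K:.4f}   U {wb.U_percent:.2f}%")
print(f"K shuffled  {sh.K_mean:.2e} +- {sh.K_sd:.1e}")
print(f"nodes with K_i = 1 (only balanced walks): {len(wb.highest_balance_nodes)}")
print("top 5 genes by balance degree K_i:")
for g in wb.ranked_nodes[:5]:
    i = net.gene_ids.index(g)
    print(f"  {g}  K_i = {wb.node_balance[i]:.6f}")
# K far above the shuffled baseline means the sign arrangement respects
# balance over long cycles, not just in triangles: random sign placement
# on the same topology collapses K toward zero.
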
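"""Select DNB member genes from local SLE scores at the critical time.

Ranks every gene by the mean perturbation of its local network at the
planted critical time and keeps the top fraction; the overlap with the
planted module shows how informative the per-gene scores are.
"""

from dnbsle import (
    SyntheticConfig,
    generate_network,
    local_scores_at,
    rank_local_scores,
    select_dnb_members,
    simulate_timecourse,
)

config = SyntheticConfig(seed=7)
network, module = generate_network(config)
data, truth = simulate_timecourse(network, module, config)

locals_by_case = local_scores_at(network, data, truth.t_star)
ranked = rank_local_scores(locals_by_case)

print("top 10 genes by mean local SLE score at", truth.t_star)
for gene, score in ranked[:10]:
    mark = "*" if gene in module else " "
    print(f"  {mark} {gene}  {score:.5f}")
print("(* = planted module gene)")

result = select_dnb_members(
    ranked, rule="top_fraction", parameter=config.m / config.K,
    critical_time=truth.t_star,
)
overlap = set(result.genes) & module
print(
    f"\nselected {len(result.genes)} members; {len(overlap)} of "
    f"{len(module)} planted module genes recovered."
)
print(
    "A gene scores high when the treated sample reweights the correlations\n"
    "inside its neighbourhood and shifts its own variance; at these small\n"
    "cohort sizes the ranking is dominated by neighbourhood size, so module\n"
    "recovery from local scores alone is weak."
)
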
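"""Gene-set statistics: ORA, stress-response fractions, ribosome test.

Overrepresentation analysis uses the strict thresholds overlap > 3,
p < 0.001 and enrichment ratio > 1.5. The environmental stress response
(ESR) analysis reads out what fraction of the ~300 stress-induced (iESR)
and ~600 stress-repressed (rESR) transcripts a strain activates or
represses.
"""

import numpy as np

from priontx import GeneSet, esr_analysis, kegg_ribosome_test, ora, tf_gene_proportion_test
from priontx.types import DEGCall

rng = np.random.default_rng(0)
universe = {f"g{i}" for i in range(6000)}

# --- ORA ---------------------------------------------------------------
pathway = GeneSet("carbohydrate_metabolism", frozenset(f"g{i}" for i in range(80)))
decoy = GeneSet("decoy", frozenset(rng.choice(sorted(universe), 80, replace=False)))
query = {f"g{i}" for i in range(30)} | set(rng.choice(sorted(universe), 70, replace=False))
for r in ora(query & universe, [pathway, decoy], universe):
    flag = "significant" if r.significant else "not significant"
    print(f"{r.set_name}: overlap {r.k}/{r.K}, ratio {r.enrichment_ratio:.1f}, "
          f"p={r.p:.2e} -> {flag}")

# --- ESR fractions -----------------------------------------------------
iesr = GeneSet("iESR", frozenset(f"g{i}" for i in range(5000, 5300)))
resr = GeneSet("rESR", frozenset(f"g{i}" for i in range(5300, 5900)))
directions = {g: "unchanged" for g in universe}
for g in list(resr.members)[:54]:
    directions[g] = "up"  # a prion-like pattern: rESR activated
for g in list(iesr.members)[:140]:
    directions[g] = "down"  # ... while iESR is repressed
calls = [
    DEGCall(g, "prion_vs_wt", {"up": 2.0, "down": -2.0}.get(d, 0.0), 1e-6, 1e-5, d)
    for g, d in directions.items()
]
esr = esr_analysis(calls, iesr, resr, universe)
for s in ("iESR", "rESR"):
    a, r = esr[s]["activated"], esr[s]["repressed"]
    print(f"{s}: {a['percent']}% activated (p={a['p']:.1e}), "
          f"{r['percent']}% repressed (p={r['p']:.1e})")
# activated rESR plus repressed iESR = the inverse of a stress response

# --- KEGG ribosome test ------------------------------------------------
ribosome = GeneSet("kegg_ribosome", frozenset(f"g{i}" for i in range(4000, 4150)))
subgroups = {
    "deletion_down": set(list(ribosome.members)[:90])
    | set(rng.choice(sorted(universe), 200, replace=False)),
    "prion_up": set(rng.choice(sorted(universe - ribosome.members), 250, replace=False)),
}
for name, res in kegg_ribosome_test(subgroups, ribosome, universe).items():
    print(f"ribosome overrepresentation in {name}: k={res.k}, p={res.p:.1e}, "
          f"significant={res.significant}")

# --- TF-gene proportion test -------------------------------------------
tf_genes = set(rng.choice(sorted(universe), 183, replace=False))
deg_down = set(rng.choice(sorted(tf_genes), 15, replace=False)) | set(
    rng.choice(sorted(universe - tf_genes), 480, replace=False)
)
res = tf_gene_proportion_test(set(), deg_down, tf_genes, universe)
print(
    f"TF genes among down DEGs: {res['down']['n_tf_in_degs']}/{res['down']['n_degs']} "
    f"({100 * res['down']['fraction']:.1f}% vs genome {100 * res['down']['genome_fraction']:.1f}%), "
    f"p={res['down']['p']:.3f}"
)
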
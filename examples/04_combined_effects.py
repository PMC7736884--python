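"""Combined-effect classification and regulator queries.

For targets of aggregated TFs, the observed prion-strain direction is
checked against two explanation sources: the deletion strain's direction
(a proxy for losing the remodeler's function) and the aggregated TFs'
predicted effects. Also demonstrates querying a gene's altered upstream
regulators and counting interaction partners.
"""

from priontx import (
    RegulonEdge,
    TFAlteration,
    classify_interactions,
    combined_classification,
    interpretability_fraction,
    regulator_network_query,
)

edges = [
    RegulonEdge("TF1", "gA", "activator"),
    RegulonEdge("TF1", "gB", "activator"),
    RegulonEdge("TF2", "gC", "inhibitor"),
    RegulonEdge("TF2", "gD", "inhibitor"),
]
# observed directions per strain
dir_prion = {"gA": "down", "gB": "down", "gC": "up", "gD": "up", "gE": "unchanged"}
dir_deletion = {"gA": "down", "gB": "unchanged", "gC": "unchanged", "gD": "down", "gE": "up"}

calls, subgroups = combined_classification(dir_prion, dir_deletion, ["TF1", "TF2"], edges)
print("gene  prion  deletion  explanation")
for c in calls:
    print(f"{c.gene_id:>4}  {c.dir_prion:>5}  {c.dir_deletion:>8}  {c.explanation}")
out = interpretability_fraction(calls)
print(
    f"\n{out['n_interpretable']}/{out['n_scored']} targets interpretable "
    f"({100 * out['fraction']:.1f}%) — gA by both sources, gB by TF1's "
    "aggregation alone, gC by TF2's aggregation, gD by both-conflicting "
    "sources resolved through the aggregated inhibitor"
)

# --- which altered regulators act on a gene? ---------------------------
upstream = [
    RegulonEdge("ACT1", "SWI1", "activator"),
    RegulonEdge("ACT2", "SWI1", "activator"),
    RegulonEdge("ACT3", "SWI1", "activator"),
    RegulonEdge("REP1", "SWI1", "inhibitor"),
]
alterations = [
    TFAlteration("ACT1", "up"),
    TFAlteration("ACT2", "up"),
    TFAlteration("ACT3", "up"),
    TFAlteration("REP1", "down"),
]
q = regulator_network_query("SWI1", upstream, alterations)
print(
    f"\nSWI1 query: {len(q['altered'])} of {q['n_regulators']} regulators altered, "
    f"net expectation: {q['net_expectation']}"
)
# three upregulated activators plus one downregulated repressor all push
# the same way — consistent with elevated transcription of the gene.

# --- interaction-partner bookkeeping -----------------------------------
genetic = {f"p{i}" for i in range(261)}
physical = {f"p{i}" for i in range(10)} | {f"q{i}" for i in range(52)}
counts = classify_interactions(genetic, physical)
print(
    f"\ninteraction partners: {counts['n_genetic']} genetic + {counts['n_physical']} "
    f"physical - {counts['both']} shared = {counts['total']} proteins"
)
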
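"""Combined-effect classification: prion-state transcription explained by
loss of the chromatin remodeler plus TF aggregation.

The logic: the regulatory effect of losing Swi1 function on a gene is
proxied by that gene's direction in the deletion strain; the effect of
TF aggregation is predicted from signed regulon edges (aggregated
activator -> target down, aggregated inhibitor -> target up). A target's
observed prion-strain direction is interpretable when it matches either
source; "combination" records that both matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .attribution import predict_direction
from .types import RegulonEdge, TFAlteration


@dataclass(frozen=True)
class CombinedCall:
    gene_id: str
    dir_prion: str
    dir_deletion: str
    tf_predictions: frozenset[str]
    subgroup: tuple[str, str]
    interpretable: bool
    explanation: str  # swi1_loss | tf_aggregation | combination | none


def combined_classification(
    deg_prion: Mapping[str, str],
    deg_deletion: Mapping[str, str],
    aggregated_tfs: Sequence[str],
    regulons: Sequence[RegulonEdge],
    targets_only: bool = True,
) -> tuple[list[CombinedCall], dict[tuple[str, str], int]]:
    """Classify genes by joint (prion, deletion) direction and decide
    interpretability under combined Swi1-loss and TF-aggregation effects.

    ``deg_prion`` / ``deg_deletion`` map gene -> direction over aligned
    universes. With ``targets_only`` the call list is restricted to
    targets of the aggregated TFs that are a DEG in at least one strain
    (the joint patterns then span 6 subgroups, since the double-unchanged
    cell is excluded and targets are conditioned on one non-null axis).
    """
    if set(deg_prion) != set(deg_deletion):
        raise ValueError("gene universes of the two contrasts differ")
    tf_ids = {e.tf_id for e in regulons}
    missing = set(aggregated_tfs) - tf_ids
    if missing:
        raise ValueError(f"aggregated TFs absent from regulons: {sorted(missing)}")

    alts = {tf: TFAlteration(tf, aggregation="aggregated") for tf in aggregated_tfs}
    tf_preds: dict[str, set[str]] = {}
    target_space: set[str] = set()
    for e in regulons:
        if e.tf_id not in alts:
            continue
        target_space.add(e.target_id)
        dirs = predict_direction(alts[e.tf_id], e.role)
        if dirs:
            tf_preds.setdefault(e.target_id, set()).update(dirs)

    calls: list[CombinedCall] = []
    counts: dict[tuple[str, str], int] = {}
    for gene in sorted(deg_prion):
        dp, dd = deg_prion[gene], deg_deletion[gene]
        if targets_only and gene not in target_space:
            continue
        if dp == "unchanged" and dd == "unchanged":
            continue
        preds = frozenset(tf_preds.get(gene, set()))
        swi1_match = dp != "unchanged" and dp == dd
        tf_match = dp in preds
        if swi1_match and tf_match:
            explanation = "combination"
        elif swi1_match:
            explanation = "swi1_loss"
        elif tf_match:
            explanation = "tf_aggregation"
        else:
            explanation = "none"
        subgroup = (dp, dd)
        counts[subgroup] = counts.get(subgroup, 0) + 1
        calls.append(
            CombinedCall(
                gene_id=gene,
                dir_prion=dp,
                dir_deletion=dd,
                tf_predictions=preds,
                subgroup=subgroup,
                interpretable=explanation != "none",
                explanation=explanation,
            )
        )
    return calls, counts


def interpretability_fraction(calls: Sequence[CombinedCall]) -> dict:
    """Fraction of calls interpretable by any source, with subgroup
    stratification. Genes unchanged in the prion strain form their own
    subgroups and are excluded from the fraction's denominator (their
    prion-state transcription poses no pattern to explain)."""
    if not calls:
        raise ValueError("empty call list")
    scored = [c for c in calls if c.dir_prion != "unchanged"]
    n_interp = sum(c.interpretable for c in scored)
    by_subgroup: dict[str, dict] = {}
    for c in calls:
        key = f"{c.dir_prion}/{c.dir_deletion}"
        d = by_subgroup.setdefault(key, {"n": 0, "interpretable": 0})
        d["n"] += 1
        if c.dir_prion != "unchanged":
            d["interpretable"] += int(c.interpretable)
    return {
        "n_total": len(calls),
        "n_scored": len(scored),
        "n_interpretable": n_interp,
        "fraction": n_interp / len(scored) if scored else None,
        "by_subgroup": by_subgroup,
        "by_explanation": {
            expl: sum(1 for c in scored if c.explanation == expl)
            for expl in ("swi1_loss", "tf_aggregation", "combination", "none")
        },
    }


def regulator_network_query(
    gene: str,
    regulons: Sequence[RegulonEdge],
    alterations: Sequence[TFAlteration],
) -> dict:
    """List the altered upstream regulators of one gene with the
    direction each implies, and the net expectation when they agree."""
    alt_by_tf = {a.tf_id: a for a in alterations if a.is_altered}
    upstream = [e for e in regulons if e.target_id == gene]
    rows = []
    implied: set[str] = set()
    for e in upstream:
        alt = alt_by_tf.get(e.tf_id)
        if alt is None:
            continue
        dirs = predict_direction(alt, e.role)
        rows.append(
            {
                "regulator": e.tf_id,
                "role": e.role,
                "transcriptional": alt.transcriptional,
                "aggregation": alt.aggregation,
                "implied": sorted(dirs),
            }
        )
        implied.update(dirs)
    if not implied:
        net = "none"
    elif implied == {"up"}:
        net = "up"
    elif implied == {"down"}:
        net = "down"
    else:
        net = "ambiguous"
    return {
        "gene": gene,
        "n_regulators": len({e.tf_id for e in upstream}),
        "altered": rows,
        "net_expectation": net,
    }


def classify_interactions(genetic_partners: set[str], physical_partners: set[str]) -> dict:
    """Partition interaction partners into genetic-only, physical-only
    and both; the total follows inclusion-exclusion."""
    both = genetic_partners & physical_partners
    return {
        "genetic_only": len(genetic_partners - physical_partners),
        "physical_only": len(physical_partners - genetic_partners),
        "both": len(both),
        "n_genetic": len(genetic_partners),
        "n_physical": len(physical_partners),
        "total": len(genetic_partners) + len(physical_partners) - len(both),
    }
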
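"""Synthetic fixtures that realize stated summary counts.

These builders construct minimal DEG-call lists, signed regulons and TF
alteration records whose attribution arithmetic comes out at specified
union counts — e.g. "N up-regulated targets of altered TFs, M of them
sign-consistent". They exist so that summary-level results (counts read
off published tables or figures) can be pushed through the full
attribution machinery instead of being re-derived with ad-hoc division.
All gene and TF identifiers are synthetic.
"""

from __future__ import annotations

from .types import DEGCall, RegulonEdge, TFAlteration


def attribution_fixture(
    n_up: int,
    n_up_interpretable: int,
    n_down: int,
    n_down_interpretable: int,
    aggregated: bool = False,
    prefix: str = "F",
) -> tuple[list[DEGCall], list[TFAlteration], list[RegulonEdge]]:
    """Build (deg_calls, alterations, regulons) whose interpretability
    report has exactly the requested per-direction target and
    interpretable-union counts.

    Four synthetic TFs are used, one per (observed direction x
    interpretable?) cell: interpretable up-targets hang off a TF whose
    state predicts "up" through its edges, non-interpretable ones off a
    TF predicting the opposite of what is observed, and likewise for the
    down side. With ``aggregated`` the TFs are aggregation-only (their
    predictions then come from loss of function: activator -> down,
    inhibitor -> up).
    """
    if n_up_interpretable > n_up or n_down_interpretable > n_down:
        raise ValueError("interpretable counts cannot exceed target counts")

    if aggregated:
        # aggregated TFs predict: activator edge -> down, inhibitor -> up
        def tf(i: str) -> TFAlteration:
            return TFAlteration(f"{prefix}TF{i}", "none", "aggregated")

        role_predicting = {"up": "inhibitor", "down": "activator"}
    else:
        # transcriptionally upregulated TFs predict: activator -> up,
        # inhibitor -> down
        def tf(i: str) -> TFAlteration:
            return TFAlteration(f"{prefix}TF{i}", "up", "unknown")

        role_predicting = {"up": "activator", "down": "inhibitor"}

    calls: list[DEGCall] = []
    alterations: list[TFAlteration] = []
    edges: list[RegulonEdge] = []
    groups = [
        ("up", "up", n_up_interpretable, "a"),  # observed up, predicted up
        ("up", "down", n_up - n_up_interpretable, "b"),  # observed up, predicted down
        ("down", "down", n_down_interpretable, "c"),
        ("down", "up", n_down - n_down_interpretable, "d"),
    ]
    for observed, predicted, count, tag in groups:
        if count == 0:
            continue
        alteration = tf(tag)
        alterations.append(alteration)
        role = role_predicting[predicted]
        for i in range(count):
            gene = f"{prefix}{tag}{i}"
            edges.append(RegulonEdge(alteration.tf_id, gene, role))
            lfc = 2.0 if observed == "up" else -2.0
            calls.append(DEGCall(gene, "prion_vs_wt", lfc, 1e-6, 1e-5, observed))
    return calls, alterations, edges


def overlap_fixture(n_a: int, n_b: int, n_shared: int, prefix: str = "O") -> tuple[set[str], set[str]]:
    """Two gene-id sets with the requested sizes and intersection."""
    if n_shared > min(n_a, n_b):
        raise ValueError("intersection cannot exceed either set size")
    shared = {f"{prefix}s{i}" for i in range(n_shared)}
    a = shared | {f"{prefix}a{i}" for i in range(n_a - n_shared)}
    b = shared | {f"{prefix}b{i}" for i in range(n_b - n_shared)}
    return a, b
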
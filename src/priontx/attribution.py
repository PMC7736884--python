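"""TF-target overrepresentation and sign-consistency interpretability.

The central question: how much of a strain's differential expression can
be attributed to its altered transcription factors? A DEG that is a
documented target of at least one altered TF is "interpretable" when its
observed direction matches the direction predicted from that TF's state
combined with the signed edge role:

    predicted = (TF effective sign) x (edge role sign)

where an upregulated TF has effective sign +1, a downregulated or
aggregated TF -1 (aggregation = loss of regulatory output), activator
edges have role sign +1 and inhibitor edges -1; dual-role edges predict
both directions. Counts are unique unions over genes — a gene explained
by several TFs counts once — reported separately for up- and
down-regulated targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .types import DEGCall, RegulonEdge, TFAlteration, regulon_index


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for overlap k
    between a set of K successes and a draw of n from a population of N.
    Equals the one-sided Fisher exact p of the corresponding 2x2 table."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class TFEnrichmentRow:
    """One TF's target overrepresentation among a DEG list.

    user_pct: the TF's DEG-target count as a percent of the DEG list;
    ck_pct: the same count as a percent of the TF's full regulon.
    """

    tf_id: str
    n_targets_in_degs: int
    user_pct: float
    ck_pct: float
    p: float
    n_up: int
    n_down: int
    n_interpretable: int = 0
    ratio_pct: float | None = None
    enriched: bool = False


@dataclass
class AttributionReport:
    """Interpretability of DEG targets of altered TFs, per direction and
    per TF. ``n_targets``/``n_interpretable`` are unique unions over
    genes; fractions are None when a denominator is zero."""

    n_targets_up: int
    n_interpretable_up: int
    n_targets_down: int
    n_interpretable_down: int
    per_tf: list[TFEnrichmentRow]
    conflicts: int
    interpretable_genes_up: set[str] = field(default_factory=set)
    interpretable_genes_down: set[str] = field(default_factory=set)

    @property
    def fraction_up(self) -> float | None:
        return self.n_interpretable_up / self.n_targets_up if self.n_targets_up else None

    @property
    def fraction_down(self) -> float | None:
        return (
            self.n_interpretable_down / self.n_targets_down if self.n_targets_down else None
        )

    @property
    def n_targets_total(self) -> int:
        return self.n_targets_up + self.n_targets_down

    def to_dict(self) -> dict:
        return {
            "up": {
                "n_targets": self.n_targets_up,
                "n_interpretable": self.n_interpretable_up,
                "fraction": self.fraction_up,
            },
            "down": {
                "n_targets": self.n_targets_down,
                "n_interpretable": self.n_interpretable_down,
                "fraction": self.fraction_down,
            },
            "total_targets": self.n_targets_total,
            "conflicts": self.conflicts,
        }


def tf_target_overrep(
    regulons: Sequence[RegulonEdge],
    deg_genes: set[str],
    universe: set[str],
    p_cut: float = 0.001,
    deg_directions: dict[str, str] | None = None,
) -> list[TFEnrichmentRow]:
    """Per-TF hypergeometric overrepresentation of regulon targets among
    a DEG list; rows sorted ascending by p (ties by tf_id)."""
    if not universe:
        raise ValueError("empty universe")
    if not deg_genes <= universe:
        raise ValueError("deg_genes must be a subset of the universe")
    rows: list[TFEnrichmentRow] = []
    for tf, edges in regulon_index(regulons).items():
        targets = {e.target_id for e in edges} & universe
        if not targets:
            continue
        hits = targets & deg_genes
        k = len(hits)
        p = hypergeom_upper(k, len(targets), len(deg_genes), len(universe)) if deg_genes else 1.0
        n_up = n_down = 0
        if deg_directions:
            n_up = sum(1 for g in hits if deg_directions.get(g) == "up")
            n_down = sum(1 for g in hits if deg_directions.get(g) == "down")
        rows.append(
            TFEnrichmentRow(
                tf_id=tf,
                n_targets_in_degs=k,
                user_pct=round(100.0 * k / len(deg_genes), 1) if deg_genes else 0.0,
                ck_pct=round(100.0 * k / len(targets), 1),
                p=p,
                n_up=n_up,
                n_down=n_down,
                enriched=p < p_cut,
            )
        )
    rows.sort(key=lambda r: (r.p, r.tf_id))
    return rows


def predict_direction(alteration: TFAlteration, role: str) -> frozenset[str]:
    """Directions predicted for a target of an altered TF through one
    signed edge. The TF contributes effective sign +1 when its gene is
    upregulated, -1 when downregulated, and -1 when aggregated; a TF that
    is both up and aggregated contributes both signs. Dual-role edges
    predict both orientations of each contribution."""
    if role not in {"activator", "inhibitor", "dual"}:
        raise ValueError(f"unknown role {role!r}")
    tf_signs: set[int] = set()
    if alteration.transcriptional == "up":
        tf_signs.add(+1)
    elif alteration.transcriptional == "down":
        tf_signs.add(-1)
    if alteration.aggregation == "aggregated":
        tf_signs.add(-1)
    if not tf_signs:
        return frozenset()
    role_signs = {"activator": {+1}, "inhibitor": {-1}, "dual": {+1, -1}}[role]
    return frozenset(
        "up" if ts * rs > 0 else "down" for ts in tf_signs for rs in role_signs
    )


def interpretability_score(
    deg_calls: Sequence[DEGCall],
    alterations: Sequence[TFAlteration],
    regulons: Sequence[RegulonEdge],
) -> AttributionReport:
    """Score each DEG that is a target of at least one altered TF for
    sign consistency with the TFs' predicted effects.

    Genes targeted only by unaltered TFs are outside the denominators.
    The conflict count is the number of scored genes predicted both up
    and down by different altered TFs (or a dual edge).
    """
    alt_by_tf = {a.tf_id: a for a in alterations if a.is_altered}
    tf_ids = {e.tf_id for e in regulons}
    missing = set(alt_by_tf) - tf_ids
    if missing:
        raise ValueError(f"altered TFs absent from regulons: {sorted(missing)}")

    observed = {c.gene_id: c.direction for c in deg_calls if c.direction != "unchanged"}
    predictions: dict[str, set[str]] = {}
    predicted_by: dict[str, dict[str, set[str]]] = {}  # gene -> tf -> dirs
    for e in regulons:
        alt = alt_by_tf.get(e.tf_id)
        if alt is None or e.target_id not in observed:
            continue
        dirs = predict_direction(alt, e.role)
        if not dirs:
            continue
        predictions.setdefault(e.target_id, set()).update(dirs)
        predicted_by.setdefault(e.target_id, {}).setdefault(e.tf_id, set()).update(dirs)

    up_targets = {g for g in predictions if observed[g] == "up"}
    down_targets = {g for g in predictions if observed[g] == "down"}
    interp_up = {g for g in up_targets if "up" in predictions[g]}
    interp_down = {g for g in down_targets if "down" in predictions[g]}
    conflicts = sum(1 for g in predictions if predictions[g] >= {"up", "down"})

    per_tf: list[TFEnrichmentRow] = []
    universe_degs = set(observed)
    by_tf = regulon_index(regulons)
    for tf, alt in alt_by_tf.items():
        targets = {e.target_id for e in by_tf.get(tf, [])}
        hits = targets & universe_degs
        n_up = sum(1 for g in hits if observed[g] == "up")
        n_down = len(hits) - n_up
        n_interp = sum(
            1 for g in hits if observed[g] in predicted_by.get(g, {}).get(tf, set())
        )
        per_tf.append(
            TFEnrichmentRow(
                tf_id=tf,
                n_targets_in_degs=len(hits),
                user_pct=round(100.0 * len(hits) / len(universe_degs), 1)
                if universe_degs
                else 0.0,
                ck_pct=round(100.0 * len(hits) / len(targets), 1) if targets else 0.0,
                p=1.0,  # enrichment p is computed against a universe in build_tf_table
                n_up=n_up,
                n_down=n_down,
                n_interpretable=n_interp,
                ratio_pct=round(100.0 * n_interp / len(hits), 1) if hits else None,
            )
        )

    return AttributionReport(
        n_targets_up=len(up_targets),
        n_interpretable_up=len(interp_up),
        n_targets_down=len(down_targets),
        n_interpretable_down=len(interp_down),
        per_tf=per_tf,
        conflicts=conflicts,
        interpretable_genes_up=interp_up,
        interpretable_genes_down=interp_down,
    )


def build_tf_table(
    report: AttributionReport,
    deg_genes: set[str],
    regulons: Sequence[RegulonEdge],
    universe: set[str],
) -> pd.DataFrame:
    """Per-TF summary table: enrichment p, User%, CK%, target counts and
    interpretable ratio, ordered ascending by p (ties by tf_id)."""
    by_tf = regulon_index(regulons)
    records = []
    for row in report.per_tf:
        targets = {e.target_id for e in by_tf.get(row.tf_id, [])} & universe
        p = hypergeom_upper(
            row.n_targets_in_degs, len(targets), len(deg_genes), len(universe)
        )
        records.append(
            {
                "tf_id": row.tf_id,
                "user_pct": row.user_pct,
                "ck_pct": row.ck_pct,
                "p": p,
                "total": row.n_targets_in_degs,
                "n_up": row.n_up,
                "n_down": row.n_down,
                "n_interpretable": row.n_interpretable,
                "ratio_pct": row.ratio_pct,
            }
        )
    df = pd.DataFrame.from_records(records)
    if len(df):
        df = df.sort_values(["p", "tf_id"]).reset_index(drop=True)
    return df
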
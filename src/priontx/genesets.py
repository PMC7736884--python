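"""Gene-set statistics: overrepresentation analysis (ORA), the TF-gene
proportion test, KEGG-ribosome overrepresentation, and environmental
stress response (ESR) fraction analysis.

All overrepresentation tests are one-sided upper-tail hypergeometric
(equivalently one-sided Fisher exact); the between-direction comparison
of TF-gene content is two-sided. Benjamini-Hochberg adjusted p-values
are reported alongside raw ones, but significance calls follow raw-p
cutoffs (with the ORA's additional minimum-overlap and minimum-
enrichment conditions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .attribution import hypergeom_upper
from .types import DEGCall, GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap
    K: int  # set size (within universe)
    n: int  # query size
    N: int  # universe size
    enrichment_ratio: float
    p: float
    p_adj: float
    significant: bool


def ora(
    query: set[str],
    sets: Sequence[GeneSet],
    universe: set[str],
    min_overlap: int = 3,
    p_cut: float = 0.001,
    min_enrichment: float = 1.5,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of a query list against gene sets.

    Significance requires overlap strictly greater than ``min_overlap``,
    p strictly below ``p_cut`` and enrichment ratio (k/n)/(K/N) strictly
    above ``min_enrichment``. Set members outside the universe are
    intersected away. Results sorted ascending by p.
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n, N = len(query), len(universe)
    raw: list[tuple[GeneSet, int, int, float, float]] = []
    for s in sets:
        members = s.members & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        p = hypergeom_upper(k, K, n, N) if n else 1.0
        ratio = (k / n) / (K / N) if n else 0.0
        raw.append((s, k, K, p, ratio))
    if not raw:
        return []
    p_adj = multipletests([r[3] for r in raw], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            set_name=s.name,
            k=k,
            K=K,
            n=n,
            N=N,
            enrichment_ratio=ratio,
            p=p,
            p_adj=float(pa),
            significant=(k > min_overlap and p < p_cut and ratio > min_enrichment),
        )
        for (s, k, K, p, ratio), pa in zip(raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def tf_gene_proportion_test(
    deg_up: set[str],
    deg_down: set[str],
    tf_genes: set[str],
    universe: set[str],
) -> dict:
    """Are TF genes overrepresented among up- / down-regulated DEGs
    relative to the genome-wide TF-gene ratio?

    Per direction: one-sided Fisher exact of (TF, non-TF) x (in DEG
    list, rest of universe). Plus a two-sided 2x2 comparison of TF-gene
    content between the two directions.
    """
    if not tf_genes <= universe:
        raise ValueError("tf_genes must be a subset of the universe")
    out: dict = {}
    for name, degs in (("up", deg_up), ("down", deg_down)):
        k = len(degs & tf_genes)
        table = [
            [k, len(degs) - k],
            [len(tf_genes) - k, len(universe) - len(degs) - (len(tf_genes) - k)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        out[name] = {
            "n_degs": len(degs),
            "n_tf_in_degs": k,
            "fraction": k / len(degs) if degs else 0.0,
            "genome_fraction": len(tf_genes) / len(universe),
            "p": float(p),
        }
    k_up = len(deg_up & tf_genes)
    k_down = len(deg_down & tf_genes)
    table = [[k_up, len(deg_up) - k_up], [k_down, len(deg_down) - k_down]]
    _, p_cmp = stats.fisher_exact(table, alternative="two-sided")
    out["comparison_p"] = float(p_cmp)
    return out


def esr_analysis(
    deg_calls: Sequence[DEGCall],
    iesr: GeneSet,
    resr: GeneSet,
    universe: set[str],
) -> dict:
    """Fractions of stress-induced (iESR) and stress-repressed (rESR)
    genes that are activated or repressed in a strain, with upper-tail
    hypergeometric p against the universe background."""
    if iesr.members & resr.members:
        raise ValueError("iESR and rESR sets must be disjoint")
    directions = {c.gene_id: c.direction for c in deg_calls}
    up = {g for g, d in directions.items() if d == "up"}
    down = {g for g, d in directions.items() if d == "down"}
    N = len(universe)
    out: dict = {}
    for set_name, gs in (("iESR", iesr), ("rESR", resr)):
        members = gs.members & universe
        K = len(members)
        entry: dict = {"set_size": K}
        for dir_name, degs in (("activated", up & universe), ("repressed", down & universe)):
            k = len(members & degs)
            p = hypergeom_upper(k, K, len(degs), N) if degs else 1.0
            entry[dir_name] = {
                "count": k,
                "percent": round(100.0 * k / K, 1) if K else 0.0,
                "p": p,
            }
        out[set_name] = entry
    return out


def kegg_ribosome_test(
    deg_subgroups: Mapping[str, set[str]],
    ribosome_set: GeneSet,
    universe: set[str],
) -> dict[str, EnrichmentResult]:
    """One hypergeometric overrepresentation test of the KEGG ribosome
    gene set per DEG subgroup (e.g. prion-up/-down, deletion-up/-down).
    Significance at raw p < 0.05 (the convention for these targeted
    single-set tests)."""
    members = ribosome_set.members & universe
    K, N = len(members), len(universe)
    out: dict[str, EnrichmentResult] = {}
    for name, degs in deg_subgroups.items():
        degs = degs & universe
        k = len(members & degs)
        p = hypergeom_upper(k, K, len(degs), N) if degs else 1.0
        ratio = (k / len(degs)) / (K / N) if degs and K else 0.0
        out[name] = EnrichmentResult(
            set_name=ribosome_set.name,
            k=k,
            K=K,
            n=len(degs),
            N=N,
            enrichment_ratio=ratio,
            p=p,
            p_adj=p,
            significant=p < 0.05,
        )
    return out
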
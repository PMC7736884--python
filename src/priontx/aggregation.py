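"""Screening of aggregation-prone TFs and aggregation-as-loss-of-function
attribution.

Candidate selection combines two external predictors — a CamSol-style
intrinsic solubility variant score and a pWALTZ prion-core score — with
the N/Q (asparagine + glutamine) content of the protein sequence. Both
predictor scores are consumed from files; only the threshold logic and
the sequence composition are computed here. A TF passes when

    camsol < 1.5   OR   (pwaltz > 73.5  AND  N+Q fraction > 0.20)

with strict inequalities at every threshold; a missing score fails its
branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .attribution import AttributionReport, interpretability_score
from .types import DEGCall, RegulonEdge, TFAlteration

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AggregationCandidate:
    tf_id: str
    camsol_score: float | None = None
    pwaltz_score: float | None = None
    nq_fraction: float | None = None


@dataclass(frozen=True)
class FociCount:
    """Cells with visible fluorescent foci out of cells scored, for one
    TF fusion in one strain."""

    tf_id: str
    strain: str
    cells_with_foci: int
    cells_total: int

    def __post_init__(self) -> None:
        if self.cells_with_foci > self.cells_total:
            raise ValueError("cells_with_foci cannot exceed cells_total")


def nq_content(sequence: str) -> float:
    """Fraction of residues that are asparagine (N) or glutamine (Q)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"illegal residues in sequence: {sorted(bad)}")
    return (seq.count("N") + seq.count("Q")) / len(seq)


def candidate_filter(
    c: AggregationCandidate,
    camsol_cut: float = 1.5,
    pwaltz_cut: float = 73.5,
    nq_cut: float = 0.20,
) -> bool:
    """Apply the aggregation-prone screening rule (strict inequalities).

    A missing score makes its branch fail; if every score is missing the
    candidate cannot be evaluated at all and an error is raised.
    """

    def _present(x: float | None) -> bool:
        return x is not None and not (isinstance(x, float) and math.isnan(x))

    has_camsol = _present(c.camsol_score)
    has_pwaltz = _present(c.pwaltz_score) and _present(c.nq_fraction)
    if not has_camsol and not _present(c.pwaltz_score) and not _present(c.nq_fraction):
        raise ValueError(f"{c.tf_id}: no usable scores")
    camsol_pass = has_camsol and c.camsol_score < camsol_cut
    pwaltz_pass = has_pwaltz and c.pwaltz_score > pwaltz_cut and c.nq_fraction > nq_cut
    return camsol_pass or pwaltz_pass


def foci_frequency_test(a: FociCount, b: FociCount) -> dict:
    """Compare foci frequencies between two strains for one TF with a
    two-sided Fisher exact test on the 2x2 (foci / no foci x strain)."""
    if a.tf_id != b.tf_id:
        raise ValueError("foci counts compare different TFs")
    if a.strain == b.strain:
        raise ValueError("foci counts must come from different strains")
    if a.cells_total == 0 or b.cells_total == 0:
        raise ValueError("zero cells scored")
    table = [
        [a.cells_with_foci, a.cells_total - a.cells_with_foci],
        [b.cells_with_foci, b.cells_total - b.cells_with_foci],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    fa = a.cells_with_foci / a.cells_total
    fb = b.cells_with_foci / b.cells_total
    return {
        "tf_id": a.tf_id,
        "freq_a": fa,
        "freq_b": fb,
        "difference": fa - fb,
        "p": float(p),
    }


def aggregation_attribution(
    deg_calls: Sequence[DEGCall],
    aggregated_tfs: Sequence[str],
    regulons: Sequence[RegulonEdge],
) -> AttributionReport:
    """Attribute DEGs to TF aggregation treated as loss of function.

    Identical machinery to transcriptional interpretability scoring with
    every listed TF in the aggregated state (effective direction down):
    an aggregated activator predicts its targets down, an aggregated
    inhibitor predicts them up.
    """
    alterations = [
        TFAlteration(tf, transcriptional="none", aggregation="aggregated")
        for tf in aggregated_tfs
    ]
    return interpretability_score(deg_calls, alterations, regulons)
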
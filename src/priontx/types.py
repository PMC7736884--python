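"""Core domain types shared across the pipeline.

The vocabulary mirrors how yeast regulatory genomics is usually described:
genes carry a feature class (ORF, ncRNA, snoRNA, ...), transcription-factor
(TF) regulons are signed edge lists (activator / inhibitor / dual), and a
TF's state in a perturbed strain is summarized by its transcriptional
direction plus whether its protein is aggregated (sequestered into foci,
treated as loss of function).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = frozenset(
    {
        "ORF",
        "blocked_ORF",
        "pseudogene",
        "ncRNA",
        "tRNA",
        "snoRNA",
        "telomerase_RNA",
        "transposable_element",
    }
)

ROLES = frozenset({"activator", "inhibitor", "dual"})
EVIDENCE = frozenset({"expression", "binding", "both"})
CONDITIONS = frozenset({"wt", "prion", "deletion"})
DIRECTIONS = frozenset({"up", "down", "unchanged"})
CONTRASTS = ("prion_vs_wt", "deletion_vs_wt", "prion_vs_deletion")


@dataclass(frozen=True)
class GeneRecord:
    """Annotation for a single genomic feature."""

    gene_id: str
    name: str
    chromosome: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"unknown feature_class {self.feature_class!r} for {self.gene_id}"
            )


@dataclass(frozen=True)
class RegulonEdge:
    """A signed, documented TF -> target association."""

    tf_id: str
    target_id: str
    role: str
    evidence: str = "both"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} ({self.tf_id}->{self.target_id})")
        if self.evidence not in EVIDENCE:
            raise ValueError(
                f"unknown evidence {self.evidence!r} ({self.tf_id}->{self.target_id})"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (iESR, rESR, KEGG ribosome, GO term, ...)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class TFAlteration:
    """A TF's state in a perturbed strain relative to wild type.

    ``transcriptional`` is the direction of the TF gene's own differential
    expression; ``aggregation`` records whether the TF protein forms foci
    (aggregated = loss of regulatory output on its targets). A TF may be
    both transcriptionally altered and aggregated.
    """

    tf_id: str
    transcriptional: str = "none"
    aggregation: str = "unknown"

    def __post_init__(self) -> None:
        if self.transcriptional not in {"up", "down", "none"}:
            raise ValueError(f"bad transcriptional state {self.transcriptional!r}")
        if self.aggregation not in {"aggregated", "soluble", "unknown"}:
            raise ValueError(f"bad aggregation state {self.aggregation!r}")

    @property
    def is_altered(self) -> bool:
        return self.transcriptional != "none" or self.aggregation == "aggregated"


class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts.

    Samples carry a condition label (wt / prion / deletion) and a replicate
    index. Counts are stored as a pandas DataFrame indexed by gene id.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        condition_of: Mapping[str, str],
        replicate_of: Mapping[str, int] | None = None,
    ) -> None:
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            r, c = np.argwhere(counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at gene {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        missing = [s for s in counts.columns if s not in condition_of]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        unknown = [s for s in condition_of if s not in set(counts.columns)]
        if unknown:
            raise ValueError(f"design names unknown samples: {unknown}")
        bad = {s: c for s, c in condition_of.items() if c not in CONDITIONS}
        if bad:
            raise ValueError(f"unknown conditions: {bad}")
        self.counts = counts.astype(np.int64)
        self.condition_of = dict(condition_of)
        if replicate_of is None:
            seen: dict[str, int] = {}
            replicate_of = {}
            for s in counts.columns:
                cond = self.condition_of[s]
                seen[cond] = seen.get(cond, 0) + 1
                replicate_of[s] = seen[cond]
        self.replicate_of = dict(replicate_of)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_of[s] == condition]

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(
            self.counts[keep],
            {s: self.condition_of[s] for s in keep},
            {s: self.replicate_of[s] for s in keep},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.condition_of == other.condition_of
            and self.replicate_of == other.replicate_of
        )

    def __repr__(self) -> str:
        return f"CountMatrix({len(self.genes)} genes x {len(self.samples)} samples)"


@dataclass(frozen=True)
class DEGCall:
    """Differential-expression result for one gene in one contrast."""

    gene_id: str
    contrast: str
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


def regulon_index(edges: Sequence[RegulonEdge]) -> dict[str, list[RegulonEdge]]:
    """Group edges by TF id, preserving input order."""
    by_tf: dict[str, list[RegulonEdge]] = {}
    for e in edges:
        by_tf.setdefault(e.tf_id, []).append(e)
    return by_tf


def targets_of(edges: Sequence[RegulonEdge], tf_id: str) -> set[str]:
    return {e.target_id for e in edges if e.tf_id == tf_id}
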
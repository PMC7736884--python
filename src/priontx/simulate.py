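"""Synthetic signed regulatory networks and RNA-seq count matrices.

The generator emulates the experimental design the pipeline is built for:
three isogenic yeast strains — wild type, a prion-carrying strain, and a
gene-deletion strain — sequenced with three biological replicates each at
bulk RNA-seq depth (~15 million reads per library). A random signed
TF -> target network is drawn, a subset of TFs is "planted" as
transcriptionally up- or downregulated or as aggregated (loss of
function) in the perturbed strains, and those effects propagate exactly
one hop to direct targets with sign given by (alteration sign) x (edge
role sign). Counts are negative binomial with variance mu + phi * mu^2.

Effects deliberately do not cascade beyond direct targets: the
downstream attribution logic is one-hop sign algebra, and a one-hop
generator keeps the planted ground truth well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CountMatrix, RegulonEdge

_ROLE_SIGN = {"activator": +1, "inhibitor": -1}
_DIR_SIGN = {"up": +1, "down": -1}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the design being emulated: ~6000 yeast genes of which a
    small panel are TFs, three replicates per strain, library sizes on the
    order of 15 million reads, moderate biological dispersion (phi = 0.05,
    typical for well-behaved bulk yeast replicates), and planted two-fold
    (effect_log2fc = 1) to four-fold direct-target effects.
    """

    n_genes: int = 6000
    n_tfs: int = 30
    mean_out_degree: float = 20.0
    activator_fraction: float = 0.7
    n_replicates: int = 3
    baseline_mean_log: tuple[float, float] = (4.0, 1.5)  # lognormal (mu, sigma) of mean expression
    dispersion: float = 0.05
    planted_tf_up: dict[str, list[str]] = field(default_factory=dict)  # strain -> TF ids
    planted_tf_down: dict[str, list[str]] = field(default_factory=dict)
    planted_tf_aggregated: dict[str, list[str]] = field(default_factory=dict)
    effect_log2fc: float = 2.0
    library_size: float = 15e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.activator_fraction < 1 and self.activator_fraction != 1.0:
            raise ValueError("activator_fraction must be in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def tf_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_tfs)]


@dataclass
class GroundTruth:
    """Planted truth of a simulation: per-strain true direction of every
    gene, the TF alterations that caused them, and the edges used."""

    direction: dict[str, dict[str, str]]  # strain -> gene -> {up, down, none}
    causes: dict[str, dict[str, list[tuple[str, str]]]]  # strain -> gene -> [(tf, role)]
    alterations: dict[str, dict[str, dict[str, str]]]  # strain -> tf -> state
    edges: list[RegulonEdge]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.direction == other.direction
            and self.causes == other.causes
            and self.alterations == other.alterations
            and self.edges == other.edges
        )


def generate_network(config: SimulationConfig) -> list[RegulonEdge]:
    """Draw a random signed TF -> target network.

    Each TF's out-degree is Poisson(mean_out_degree); targets are sampled
    without replacement from all genes other than the TF itself; each edge
    is an activator with probability ``activator_fraction``, else an
    inhibitor. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array(config.gene_ids())
    edges: list[RegulonEdge] = []
    for tf in config.tf_ids():
        k = min(int(rng.poisson(config.mean_out_degree)), config.n_genes - 1)
        pool = genes[genes != tf]
        targets = rng.choice(pool, size=k, replace=False)
        roles = np.where(
            rng.random(k) < config.activator_fraction, "activator", "inhibitor"
        )
        for tgt, role in zip(targets, roles):
            edges.append(RegulonEdge(tf, str(tgt), str(role), "both"))
    return edges


def _strain_effects(
    config: SimulationConfig, edges: Sequence[RegulonEdge], strain: str
) -> tuple[dict[str, int], dict[str, list[tuple[str, str]]], dict[str, dict[str, str]]]:
    """Resolve planted TF alterations into per-gene effect signs for one
    strain. Aggregation counts as a "down" regulatory output. Conflicting
    contributions on the same gene cancel when their signs sum to zero."""
    alt: dict[str, dict[str, str]] = {}
    for tf in config.planted_tf_up.get(strain, []):
        alt.setdefault(tf, {"transcriptional": "none", "aggregation": "unknown"})[
            "transcriptional"
        ] = "up"
    for tf in config.planted_tf_down.get(strain, []):
        alt.setdefault(tf, {"transcriptional": "none", "aggregation": "unknown"})[
            "transcriptional"
        ] = "down"
    for tf in config.planted_tf_aggregated.get(strain, []):
        alt.setdefault(tf, {"transcriptional": "none", "aggregation": "unknown"})[
            "aggregation"
        ] = "aggregated"

    tf_ids = {e.tf_id for e in edges}
    unknown = set(alt) - tf_ids
    if unknown:
        raise ValueError(f"planted TFs absent from the network: {sorted(unknown)}")

    sign: dict[str, int] = {}
    causes: dict[str, list[tuple[str, str]]] = {}
    # TFs' own transcriptional alteration shows up in their own counts so
    # DEG calling can rediscover them; aggregation alone does not.
    for tf, state in alt.items():
        if state["transcriptional"] != "none":
            s = _DIR_SIGN[state["transcriptional"]]
            sign[tf] = sign.get(tf, 0) + s
            causes.setdefault(tf, []).append((tf, "self"))
    for e in edges:
        state = alt.get(e.tf_id)
        if state is None or e.role not in _ROLE_SIGN:
            continue
        tf_signs = []
        if state["transcriptional"] != "none":
            tf_signs.append(_DIR_SIGN[state["transcriptional"]])
        if state["aggregation"] == "aggregated":
            tf_signs.append(-1)
        for ts in tf_signs:
            sign[e.target_id] = sign.get(e.target_id, 0) + ts * _ROLE_SIGN[e.role]
            causes.setdefault(e.target_id, []).append((e.tf_id, e.role))
    return sign, causes, alt


def simulate_counts(
    config: SimulationConfig, edges: Sequence[RegulonEdge]
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate NB counts for the three strains and record planted truth.

    Wild-type per-gene means are lognormal; in each perturbed strain every
    affected gene's mean is multiplied by 2**(sign * effect_log2fc); all
    means are rescaled so each library's expected total equals
    ``library_size``; counts are NB(mu, phi) with variance mu + phi*mu^2.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = config.gene_ids()
    base = rng.lognormal(*config.baseline_mean_log, size=config.n_genes)

    strains = ("wt", "prion", "deletion")
    direction: dict[str, dict[str, str]] = {}
    causes: dict[str, dict[str, list[tuple[str, str]]]] = {}
    alterations: dict[str, dict[str, dict[str, str]]] = {}
    mean_by_strain: dict[str, np.ndarray] = {}
    for strain in strains:
        if strain == "wt":
            sign, cause, alt = {}, {}, {}
        else:
            sign, cause, alt = _strain_effects(config, edges, strain)
        mult = np.ones(config.n_genes)
        dirs = {}
        for i, g in enumerate(genes):
            s = int(np.sign(sign.get(g, 0)))
            if s:
                mult[i] = 2.0 ** (s * config.effect_log2fc)
            dirs[g] = {1: "up", -1: "down", 0: "none"}[s]
        direction[strain] = dirs
        causes[strain] = {g: c for g, c in cause.items() if np.sign(sign.get(g, 0)) != 0}
        alterations[strain] = alt
        mean_by_strain[strain] = base * mult

    columns: dict[str, np.ndarray] = {}
    condition_of: dict[str, str] = {}
    replicate_of: dict[str, int] = {}
    phi = config.dispersion
    for strain in strains:
        mu = mean_by_strain[strain]
        mu_scaled = mu / mu.sum() * config.library_size
        for rep in range(1, config.n_replicates + 1):
            label = f"{strain}_{rep}"
            if phi > 0:
                # NB via gamma-Poisson mixture: shape 1/phi, scale phi*mu
                lam = rng.gamma(shape=1.0 / phi, scale=phi * mu_scaled)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mu_scaled)
            columns[label] = counts.astype(np.int64)
            condition_of[label] = strain
            replicate_of[label] = rep

    cm = CountMatrix(pd.DataFrame(columns, index=genes), condition_of, replicate_of)
    gt = GroundTruth(direction, causes, alterations, list(edges))
    return cm, gt


def export_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write the planted truth as a TSV: gene, strain, true_direction,
    cause (semicolon-joined "tf:role" tokens). Genes with direction
    "none" are omitted; an effect-free truth yields a header-only file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tstrain\ttrue_direction\tcause\n")
        for strain in sorted(gt.direction):
            for gene in sorted(gt.direction[strain]):
                d = gt.direction[strain][gene]
                if d == "none":
                    continue
                cause = ";".join(
                    f"{tf}:{role}" for tf, role in gt.causes[strain].get(gene, [])
                )
                fh.write(f"{gene}\t{strain}\t{d}\t{cause}\n")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")
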
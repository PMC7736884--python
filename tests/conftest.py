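import numpy as np
import pandas as pd
import pytest

from priontx import CountMatrix, DEGCall, RegulonEdge, SimulationConfig


def make_calls(directions: dict[str, str], contrast: str = "prion_vs_wt") -> list[DEGCall]:
    """Build a DEG call list from a gene -> direction map (p-values and
    fold changes consistent with the stated direction)."""
    calls = []
    for gene, d in directions.items():
        if d == "up":
            calls.append(DEGCall(gene, contrast, 2.0, 1e-6, 1e-5, "up"))
        elif d == "down":
            calls.append(DEGCall(gene, contrast, -2.0, 1e-6, 1e-5, "down"))
        else:
            calls.append(DEGCall(gene, contrast, 0.0, 0.5, 0.8, "unchanged"))
    return calls


@pytest.fixture
def toy_counts() -> CountMatrix:
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(50)]
    cols = {}
    cond = {}
    for strain in ("wt", "prion", "deletion"):
        for rep in (1, 2, 3):
            label = f"{strain}_{rep}"
            cols[label] = rng.poisson(100, size=len(genes))
            cond[label] = strain
    return CountMatrix(pd.DataFrame(cols, index=genes), cond)


@pytest.fixture
def toy_regulons() -> list[RegulonEdge]:
    return [
        RegulonEdge("tfA", "g1", "activator"),
        RegulonEdge("tfA", "g2", "activator"),
        RegulonEdge("tfB", "g2", "activator"),
        RegulonEdge("tfB", "g3", "activator"),
    ]


@pytest.fixture
def planted_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=2000,
        n_tfs=30,
        mean_out_degree=10,
        library_size=2e6,
        planted_tf_up={"prion": ["G0000", "G0001"]},
        planted_tf_down={"prion": ["G0002"], "deletion": ["G0004"]},
        planted_tf_aggregated={"prion": ["G0003"]},
        effect_log2fc=2.0,
        dispersion=0.05,
        seed=11,
    )
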
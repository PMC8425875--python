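import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mpinet.network import MPIEdge, MPINetwork
from mpinet.stats import ExpressionCohort


def edge(m, p, role="substrate", source="test"):
    return MPIEdge(m, p, role, frozenset({source}))


@pytest.fixture
def toy_net():
    """M1 produced by P1, consumed by P2; M2 reversible with P3."""
    return MPINetwork(
        [
            edge("M1", "P1", "product"),
            edge("M1", "P2", "substrate"),
            edge("M2", "P3", "both"),
        ]
    )


def random_net(rng, n_met=20, n_prot=30, mean_degree=4, prefix=""):
    """Random bipartite net with role mix; independent of the synth module."""
    edges = []
    for i in range(n_met):
        deg = min(int(rng.integers(1, 2 * mean_degree)), n_prot)
        partners = rng.choice(n_prot, size=deg, replace=False)
        for j in partners:
            role = ["substrate", "product", "both"][int(rng.integers(3))]
            edges.append(edge(f"{prefix}M{i}", f"{prefix}P{j}", role))
    return MPINetwork(edges)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_cohort(rng, n_genes=50, n_samples=40, groups=("A", "B"), paired=False):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    expr = pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples
    )
    half = n_samples // 2
    clin = pd.DataFrame(
        {
            "group": [groups[0]] * half + [groups[1]] * (n_samples - half),
            "time": rng.exponential(1000, n_samples).round(1) + 1,
            "event": rng.integers(0, 2, n_samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    if paired:
        clin["pair_id"] = [f"pair{i % half}" for i in range(n_samples)]
    return ExpressionCohort(expr, clin)
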
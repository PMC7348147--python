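import numpy as np
import pandas as pd
import pytest

from proxisig.expression import CountMatrix


def make_count_matrix(
    counts: np.ndarray,
    genes=None,
    samples=None,
    tissue="liverish",
    lengths=None,
) -> CountMatrix:
    """Small single-tissue CountMatrix; first half of samples treated."""
    n_genes, n_samples = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    half = n_samples // 2
    ann = pd.DataFrame(
        {
            "tissue": tissue,
            "group": ["treated"] * half + ["control"] * (n_samples - half),
            "replicate": list(range(1, half + 1))
            + list(range(1, n_samples - half + 1)),
        },
        index=samples,
    )
    gl = None
    if lengths is not None:
        gl = pd.Series(lengths, index=genes, name="length")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        annotations=ann,
        gene_lengths=gl,
    )


@pytest.fixture(scope="session")
def small_simulation():
    """One shared small simulated dataset: counts, truth, network, drugs."""
    from proxisig.synthetic import (
        SimulationConfig,
        simulate_counts,
        simulate_network_and_drugs,
    )

    cfg = SimulationConfig(
        n_tissues=2,
        n_genes=400,
        n_replicates=3,
        deg_fraction=0.05,
        lfc_magnitude=3.0,
        nb_dispersion=0.01,
        network_nodes=150,
        network_attach_param=2,
        n_drugs=6,
        targets_per_drug=6,
        planted_proximity_drugs=[("drug01", 0)],
        seed=42,
    )
    cm, truth = simulate_counts(cfg)
    net, targets = simulate_network_and_drugs(cfg, truth)
    return cfg, cm, truth, net, targets
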
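import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scresponse import simulate as sim
from scresponse.containers import ExpressionMatrix, GeneSetCollection

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort reused by read-only tests: 10 samples x 40
    cells, 500 genes, 25+25 planted DEGs, pathways with 16x4 spots."""
    cfg = sim.SimConfig(
        seed=42,
        n_samples_responder=5,
        n_samples_nonresponder=5,
        cells_per_sample=40,
        n_genes=500,
        n_deg_up_responder=25,
        n_deg_up_nonresponder=25,
        pathway_spec=sim.PathwaySpec(n_pathways=12, genes_per_pathway=20, spot_genes=16, spot_pathways=4),
    )
    X, meta, truth = sim.simulate_single_cell_cohort(cfg)
    sets = sim.simulate_gene_sets(cfg)
    return {"config": cfg, "X": X, "meta": meta, "truth": truth, "sets": sets}


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        [[0.0, 2.0, 1.0], [1.0, 0.0, 3.0]],
        index=["c1", "c2"],
        columns=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture()
def tiny_sets():
    return GeneSetCollection({"P1": ["g1", "g2"], "P2": ["g2", "g3"]})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
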
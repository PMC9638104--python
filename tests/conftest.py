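import numpy as np
import pandas as pd
import pytest

import ribolens as rl


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle shared across tests."""
    return rl.simulate(rl.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def cfg():
    return rl.PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def de_results(bundle, cfg):
    """DE tables for every layer and adjacent contrast of the bundle."""
    groups = list(bundle.config.groups)
    contrasts = [(groups[i], groups[i + 1]) for i in range(len(groups) - 1)]
    out = {}
    for layer, cm in bundle.matrices.items():
        for c in contrasts:
            out[(layer, c)] = rl.nb_test(cm, c, cfg)
    return out


@pytest.fixture()
def tiny_design():
    return rl.SampleDesign.build(["Nor", "AD"], 2, ["mRNA"])


def make_cm(counts, genes, samples, design, layer="mRNA"):
    df = pd.DataFrame(np.asarray(counts), index=pd.Index(genes, name="gene_id"),
                      columns=samples)
    return rl.CountMatrix(df, design, layer)


@pytest.fixture()
def make_count_matrix():
    return make_cm
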
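import numpy as np
import pandas as pd
import pytest

from sepminer import KnowledgeBase, build_fingerprints, filter_prevalent
from sepminer.fingerprints import FingerprintTable
from sepminer.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_ds():
    """Default synthetic study: 300 drugs, two planted rules, no label noise."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def synth_fp(synth_ds):
    side_effects = {d: synth_ds.side_effects[d] for d in sorted(synth_ds.kb.drugs)}
    return filter_prevalent(build_fingerprints(side_effects, synth_ds.clustering))


@pytest.fixture()
def pathway_kb():
    """Tiny hand-built KB: d1 inhibits p1 which sits in the Endocytosis pathway."""
    kb = KnowledgeBase()
    kb.add_fact("drug_has_target", "d1", "p1", "inhibitor")
    kb.add_fact("pathway", "p1", "Endocytosis", "kegg")
    kb.add_fact("drug_has_target", "d2", "p2", "inhibitor")
    kb.add_fact("pathway", "p2", "Glycolysis", "kegg")
    kb.add_fact("drug_has_target", "d3", "p1", "activator")
    return kb


def random_table(rng: np.random.Generator, n_rows: int, n_cols: int,
                 density: float) -> FingerprintTable:
    mat = (rng.random((n_rows, n_cols)) < density).astype("int8")
    frame = pd.DataFrame(
        mat,
        index=[f"d{i}" for i in range(n_rows)],
        columns=list(range(1, n_cols + 1)),
    )
    return FingerprintTable(frame)
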
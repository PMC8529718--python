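import sys
from pathlib import Path

import pytest

# make tests/oracles.py importable from any working directory
sys.path.insert(0, str(Path(__file__).parent))

from chronoscreen.simulate import (  # noqa: E402
    SimulationConfig,
    default_reference_nodes,
    simulate_fossils,
    simulate_tree,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One 10-tip strict-clock dataset shared by read-only tests."""
    cfg = SimulationConfig(n_tips=10, seed=11, n_fossils=40)
    truth, observed = simulate_tree(cfg)
    fossils = simulate_fossils(truth, cfg)
    refs = default_reference_nodes(truth)
    return {
        "config": cfg,
        "truth": truth,
        "observed": observed,
        "fossils": fossils,
        "refs": refs,
    }


@pytest.fixture()
def toy_registry_csv(tmp_path):
    """Write a small hand-made registry CSV; returns its path."""

    def _write(rows, columns=None):
        import pandas as pd

        default_cols = [
            "record_id", "taxon", "family", "genus", "region",
            "geologic_age", "source",
        ]
        df = pd.DataFrame(rows, columns=columns or default_cols)
        path = tmp_path / "registry.csv"
        df.to_csv(path, index=False)
        return path

    return _write
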
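import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import orchard_gblup as og


@pytest.fixture(scope="session")
def small_population():
    """A compact two-orchard population shared by read-only tests."""
    cfg = og.SimulationConfig(
        n_founders_per_orchard=(20, 14),
        n_families=(12, 8),
        offspring_per_family=5,
        n_markers=240,
        n_chromosomes=3,
        chrom_length_bp=300_000,
        n_qtl=30,
        h2_target=0.4,
        missing_rate=0.05,
        seed=101,
    )
    return og.simulate_orchard_population(cfg)


@pytest.fixture()
def toy_trial():
    """Tiny hand-built pedigree + trial records for mixed-model unit tests."""
    rng = np.random.default_rng(7)
    founders = [(str(i), "0", "0") for i in range(1, 6)]
    progeny = [(str(i), "0", str((i - 6) % 5 + 1)) for i in range(6, 26)]
    ped = og.Pedigree(founders + progeny)
    ids = [str(i) for i in range(6, 26)]
    frame = pd.DataFrame(
        {
            "id": ids,
            "seed_source": ["s1" if i % 2 else "s2" for i in range(len(ids))],
            "replicate": [f"r{i % 3}" for i in range(len(ids))],
            "set": [f"s{i % 2}" for i in range(len(ids))],
            "orchard": "W",
            "y": rng.normal(10.0, 1.0, len(ids)),
        }
    )
    return ped, og.TrialData(frame, ["y"])
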
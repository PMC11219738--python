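import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from isodyn.synthetic import SimulationConfig, generate_reference


@pytest.fixture(scope="session")
def small_reference():
    """16 genes, 2 isoforms each, all eight event types, traps planted."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=16,
        artifact_rates={
            "mispriming": 0.1,
            "template_switch": 0.1,
            "truncation": 0.1,
            "fusion": 0.05,
        },
    )
    return generate_reference(cfg)


@pytest.fixture(scope="session")
def clean_reference():
    cfg = SimulationConfig(seed=7, n_genes=12)
    return generate_reference(cfg)
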
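"""Shared fixtures: tiny deterministic proteomes and one full planted run.

The expensive planted-proteome pipeline instance is session-scoped so the
end-to-end, bootstrap and refinement tests all reuse the same alignments.
"""

import pytest

from sjinet.align import ScoringConfig
from sjinet.pipeline import PipelineConfig, run_pipeline
from sjinet.records import ProteinRecord
from sjinet.synthetic import SimulationConfig, simulate_proteomes


@pytest.fixture(scope="session")
def scoring() -> ScoringConfig:
    return ScoringConfig()


@pytest.fixture(scope="session")
def tiny_proteomes() -> dict[str, list[ProteinRecord]]:
    """Two species, two obvious families plus a length-ratio violator."""
    mk = ProteinRecord
    a_core = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
    b_core = "GSHMWNSTLPQRVVDEILKAGYTTASNPWWAAG" * 3
    return {
        "spA": [
            mk("A1", "spA", a_core),
            mk("A2", "spA", b_core),
            mk("A3", "spA", a_core * 2),  # twice the family length: ratio 2.0
        ],
        "spB": [
            mk("B1", "spB", a_core[:-2] + "WW"),
            mk("B2", "spB", b_core[:-1] + "A"),
        ],
    }


@pytest.fixture(scope="session")
def planted_instance():
    """One full pipeline run on the default planted-family proteomes."""
    proteomes, truth = simulate_proteomes(SimulationConfig(rng_seed=101))
    result = run_pipeline(proteomes, PipelineConfig())
    return proteomes, truth, result
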
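"""Shared world definition and paths for the numbered analysis scripts.

The demonstration world is a mixed population: 30% of lineages are
coordinated-capable (kin cells move between states together), the rest are
purely Markovian. The chain's stationary composition is set to 90:5:5 so
the fixed-total normalization scheme matches the sorted composition, as in
the real protocol.
"""

import os

import numpy as np

from clonedyn.synthetic import SimulationConfig

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")

PI = np.array([0.90, 0.05, 0.05])
TRUE_M = 0.5 * np.eye(3) + 0.5 * np.ones((3, 1)) * PI


def world() -> SimulationConfig:
    return SimulationConfig(
        n_lineages=2560,
        initial_cells_per_lineage=500,
        true_transition_matrix=TRUE_M,
        initial_state_probs=tuple(PI),
        mode="mixed",
        mixed_fraction=0.3,
        coordination_prob=0.5,
        sort_fraction=0.5,
        seed=2021,
    )


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
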
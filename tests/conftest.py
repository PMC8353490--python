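import numpy as np
import pytest

from clonedyn import synthetic as syn
from clonedyn.amplicon import AmpliconSpec


@pytest.fixture(scope="session")
def small_world():
    """A small noiseless synthetic experiment shared across I/O tests:
    40 Markovian lineages, truth table, barcodes, sample indices."""
    cfg = syn.SimulationConfig(n_lineages=40, initial_cells_per_lineage=300, seed=123)
    truth = syn.simulate_lineages(cfg)
    rng = np.random.default_rng(99)
    barcode_map = syn.assign_barcodes(cfg.n_lineages, rng)
    samples = [(t, s) for t in cfg.timepoints for s in syn.STATES]
    index_map = syn.assign_sample_indices(samples, rng)
    return {
        "config": cfg,
        "truth": truth,
        "barcode_map": barcode_map,
        "index_map": index_map,
        "spec": AmpliconSpec(),
    }


@pytest.fixture(scope="session")
def noiseless_fastq(small_world, tmp_path_factory):
    out = tmp_path_factory.mktemp("fastq")
    paths = syn.emit_fastq(
        small_world["truth"],
        small_world["spec"],
        small_world["index_map"],
        small_world["barcode_map"],
        str(out),
        seed=5,
    )
    return paths

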
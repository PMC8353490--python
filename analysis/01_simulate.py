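"""Simulate the barcoded time course and emit amplicon FASTQ.

Writes the cultured truth table and the sorted (half-culture) table to
results/, barcode and sample-index assignments, and per-sample FASTQ under
scratch/fastq (sequencing depth 0.3 reads per sorted cell).
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import SCRATCH, results_path, world

from clonedyn import synthetic as syn
from clonedyn.amplicon import AmpliconSpec
from clonedyn.barcode_io import SampleIndexSet


def main() -> None:
    cfg = world()
    truth = syn.simulate_lineages(cfg)
    sorted_truth = syn.sort_and_sample(truth, cfg.sort_fraction, seed=2022)
    syn.write_truth_table(truth, results_path("truth.tsv"))
    syn.write_truth_table(sorted_truth, results_path("truth_sorted.tsv"))

    rng = np.random.default_rng(2023)
    barcode_map = syn.assign_barcodes(cfg.n_lineages, rng)
    samples = [(t, s) for t in cfg.timepoints for s in cfg.state_labels]
    index_map = syn.assign_sample_indices(samples, rng)
    pd.DataFrame(
        [{"lineage": k, "barcode": v} for k, v in barcode_map.items()]
    ).to_csv(results_path("barcodes.tsv"), sep="\t", index=False)
    SampleIndexSet(index_map).to_tsv(results_path("indices.tsv"))

    spec = AmpliconSpec(per_base_error_rate=0.002, reads_per_cell=0.3)
    fastq_dir = os.path.join(SCRATCH, "fastq")
    paths = syn.emit_fastq(sorted_truth, spec, index_map, barcode_map,
                           fastq_dir, seed=2024)

    per_tp = truth.groupby("timepoint")["cells"].sum()
    print(f"simulated {cfg.n_lineages} lineages over days {list(cfg.timepoints)}")
    print(f"cultured cells per day: {per_tp.to_dict()}")
    print(f"wrote {len(paths)} FASTQ samples to {fastq_dir}")


if __name__ == "__main__":
    main()
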
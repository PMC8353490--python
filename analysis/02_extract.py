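"""Filter, demultiplex and collapse the simulated FASTQ into read counts.

Reads scratch/fastq, applies the four quality criteria and Hamming-<6
collapsing, and writes results/counts.tsv plus the per-criterion QC report.
"""

import glob
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import SCRATCH, results_path

from clonedyn.amplicon import AmpliconSpec
from clonedyn.barcode_io import SampleIndexSet, extract_counts, write_qc_report


def main() -> None:
    fastq = sorted(glob.glob(os.path.join(SCRATCH, "fastq", "*.fastq")))
    if not fastq:
        raise SystemExit("run 01_simulate.py first")
    indices = SampleIndexSet.from_tsv(results_path("indices.tsv"))
    spec = AmpliconSpec(per_base_error_rate=0.002, reads_per_cell=0.3)
    counts, qc = extract_counts(fastq, indices, spec)
    counts.to_csv(results_path("counts.tsv"), sep="\t", index=False)
    write_qc_report(qc, results_path("qc.json"))
    print(f"{qc['passed']}/{qc['total_reads']} reads passed "
          f"({qc['passed'] / qc['total_reads']:.1%}); "
          f"failures by criterion: {qc['failed']}")
    print(f"{counts['barcode'].nunique()} collapsed barcodes across "
          f"{counts.groupby(['timepoint', 'state']).ngroups} samples")


if __name__ == "__main__":
    main()
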
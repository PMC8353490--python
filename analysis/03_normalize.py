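"""Normalize read counts to cell numbers and keep complete lineages.

Applies the 90:5:5 fixed-total scheme, drops lineages not detected at every
timepoint, and writes cells and state proportions to results/.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import results_path

from clonedyn.normalization import (
    filter_complete_lineages,
    normalize_counts,
    state_proportions,
)


def main() -> None:
    counts = pd.read_csv(results_path("counts.tsv"), sep="\t")
    cells = normalize_counts(counts)
    cells, retained = filter_complete_lineages(cells)
    props = state_proportions(cells)
    cells.to_csv(results_path("cells.tsv"), sep="\t", index=False)
    props.to_csv(results_path("proportions.tsv"), sep="\t", index=False)
    n_all = counts["barcode"].nunique()
    print(f"{len(retained)}/{n_all} barcodes complete at all timepoints")
    sums = cells.groupby(["timepoint", "state"])["cells"].sum().round()
    print("per-sample cell totals after normalization:")
    print(sums.unstack().to_string())


if __name__ == "__main__":
    main()
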
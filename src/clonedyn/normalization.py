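"""Fixed-total normalization of barcode read counts into cell numbers.

Each sorted (timepoint, state) sample is scaled so that its total cell count
equals a fixed per-state total, regardless of sequencing depth:

* default scheme — State1:State2:State3 = 90:5:5 out of 10^8 sorted cells
  (90,000,000 / 5,000,000 / 5,000,000);
* Markov-test scheme — the same 90:5:5 ratio scaled to 10^6 cells per
  timepoint (900,000 / 50,000 / 50,000), with floor rounding so small
  lineages drop below one cell and fall out of the testable set;
* CD24 differentiation scheme — CD24high -> 3,000,000 and CD24low ->
  1,000,000 cells (the actually sorted numbers).

A lineage is analyzable only if its summed count across the three states is
strictly positive at every timepoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import STATES

DEFAULT_SCHEME = {"State1": 90_000_000, "State2": 5_000_000, "State3": 5_000_000}
MARKOV_TEST_SCHEME = {"State1": 900_000, "State2": 50_000, "State3": 50_000}
CD24_SCHEME = {"CD24high": 3_000_000, "CD24low": 1_000_000}


def normalize_counts(
    counts: pd.DataFrame,
    scheme: dict[str, float] = DEFAULT_SCHEME,
    rounding: str = "none",
) -> pd.DataFrame:
    """Read counts -> cell numbers with fixed per-(timepoint, state) totals.

    Within each sample, cells = reads / total_reads(sample) × scheme total of
    the sample's state. ``rounding="floor"`` truncates to whole cells (used
    by the Markov-property test); ``"none"`` keeps real-valued cells.

    Parameters
    ----------
    counts
        Tidy table with columns timepoint, state, barcode (or lineage), reads.
    """
    if rounding not in ("none", "floor"):
        raise ValueError("rounding must be 'none' or 'floor'")
    missing = set(counts["state"].unique()) - set(scheme)
    if missing:
        raise KeyError(f"no scheme total for states {sorted(missing)}")

    out = counts.copy()
    out["cells"] = 0.0
    for (t, state), grp in counts.groupby(["timepoint", "state"]):
        total = grp["reads"].sum()
        if total == 0:
            continue  # all-zero sample stays all zero
        out.loc[grp.index, "cells"] = grp["reads"] / total * scheme[state]
    if rounding == "floor":
        out["cells"] = np.floor(out["cells"])
    return out.drop(columns="reads")


def filter_complete_lineages(
    table: pd.DataFrame, id_col: str = "barcode", value_col: str = "cells"
) -> tuple[pd.DataFrame, list]:
    """Keep lineages with strictly positive 3-state sum at every timepoint.

    Returns the filtered table and the sorted list of retained lineage ids.
    """
    timepoints = sorted(table["timepoint"].unique())
    sums = table.groupby([id_col, "timepoint"])[value_col].sum().unstack(fill_value=0)
    sums = sums.reindex(columns=timepoints, fill_value=0)
    keep = sums.index[(sums > 0).all(axis=1)]
    filtered = table[table[id_col].isin(keep)].reset_index(drop=True)
    return filtered, sorted(keep)


def subsample_reads(counts: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Binomial thinning of every (sample, barcode) read count.

    Robustness check: lineage-size distributions and motility should be
    stable under moderate subsampling of sequencing depth.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction outside (0, 1]")
    out = counts.copy()
    if fraction == 1.0:
        return out
    rng = np.random.default_rng(seed)
    out["reads"] = rng.binomial(out["reads"].to_numpy(), fraction)
    return out


def state_proportions(
    table: pd.DataFrame,
    id_col: str = "barcode",
    value_col: str = "cells",
    states: tuple = STATES,
) -> pd.DataFrame:
    """Cell counts -> per-(lineage, timepoint) state proportions on the simplex.

    Rows with zero total are dropped (a proportion is undefined there). The
    result has one row per (lineage, timepoint) with one column per state.
    """
    wide = (
        table.pivot_table(
            index=[id_col, "timepoint"], columns="state", values=value_col,
            aggfunc="sum", fill_value=0,
        )
        .reindex(columns=list(states), fill_value=0)
    )
    totals = wide.sum(axis=1)
    wide = wide[totals > 0]
    props = wide.div(wide.sum(axis=1), axis=0)
    props.columns.name = None
    return props.reset_index()
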
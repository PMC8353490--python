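"""Lineage dynamics on the ternary state simplex.

A lineage's composition (P1, P2, P3) is embedded in the plane as
x = P1 − P3, y = P2, placing pure State 1 at (1, 0), pure State 2 at
(0, 1) and pure State 3 at (−1, 0). Under this embedding the Euclidean
displacement between two timepoints ("motility") ranges from 0 to 2, with
the maximum attained along the State 1–State 3 axis — deliberately
up-weighting 1<->3 interconversion, the largest gene-expression change.
Percent motility is motility/2 × 100.

Lineage entropy rescales the Shannon entropy (log base 3) of a composition
so that its maximum of 1 sits at the population steady state
(0.73, 0.15, 0.12) rather than at the uniform composition, and 0 at the
three vertices: a lineage at maximal entropy is exactly where a memoryless
(Markovian) population would converge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import STATES, STEADY_STATE


def _check_simplex(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3 or np.any(p < -tol) or np.any(np.abs(p.sum(axis=-1) - 1) > tol):
        raise ValueError("not a point on the 3-state simplex")
    return np.clip(p, 0.0, 1.0)


def ternary_coords(p, embedding: str = "axis") -> tuple[float, float]:
    """Simplex point (P1, P2, P3) -> planar coordinates.

    ``axis`` (default): (P1 − P3, P2) — pure states at (1,0), (0,1), (−1,0).
    ``literal``: (P1, P2) — the variant with State 3 at the origin.
    """
    p = _check_simplex(p)
    if embedding == "axis":
        return float(p[0] - p[2]), float(p[1])
    if embedding == "literal":
        return float(p[0]), float(p[1])
    raise ValueError(f"unknown embedding {embedding!r}")


def motility(c1: tuple[float, float], c2: tuple[float, float]) -> float:
    """Euclidean displacement between two ternary positions; range [0, 2]."""
    return float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))


def percent_motility(m: float) -> float:
    return m / 2.0 * 100.0


@dataclass
class MotilityRecord:
    lineage: object
    per_transition: np.ndarray  # one motility per consecutive timepoint pair
    overall: float  # sum over transitions, in [0, 2 × n_transitions]
    percent_per_transition: np.ndarray
    decile: int = 0  # 1..10 by overall motility; assigned across lineages


def motility_table(
    proportions: pd.DataFrame,
    id_col: str = "barcode",
    embedding: str = "axis",
) -> pd.DataFrame:
    """Per-lineage per-transition motility from a state-proportion table.

    Input is tidy proportions (one row per lineage-timepoint, state columns);
    output has one row per lineage with per-transition motility columns, the
    overall motility (sum over the four transitions) and a decile rank 1–10
    by overall motility (ties broken by stable lineage-id order).
    """
    timepoints = sorted(proportions["timepoint"].unique())
    wide = proportions.set_index([id_col, "timepoint"])[list(STATES)]
    rows = []
    for lin in sorted(proportions[id_col].unique()):
        sub = wide.loc[lin]
        if not all(t in sub.index for t in timepoints):
            continue
        coords = [ternary_coords(sub.loc[t].to_numpy(), embedding) for t in timepoints]
        per = np.array([motility(coords[k], coords[k + 1]) for k in range(len(coords) - 1)])
        row = {id_col: lin, "overall": float(per.sum())}
        for k, t in enumerate(timepoints[:-1]):
            row[f"m_{t}_{timepoints[k+1]}"] = per[k]
            row[f"pct_{t}_{timepoints[k+1]}"] = percent_motility(per[k])
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    # stable sort by (overall, id) then cut into 10 near-equal groups
    table = table.sort_values(["overall", id_col], kind="stable").reset_index(drop=True)
    table["decile"] = np.minimum(10, (np.arange(len(table)) * 10) // len(table) + 1)
    return table.sort_values(id_col).reset_index(drop=True)


def shannon_entropy(probabilities, base: float = 2.0) -> float:
    """Shannon entropy with the 0·log 0 = 0 convention."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probabilities")
    if abs(p.sum() - 1) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz) / np.log(base)).sum())


@dataclass
class EntropyParams:
    steady_state: tuple = STEADY_STATE
    base: float = 3.0

    def __post_init__(self) -> None:
        pi = np.asarray(self.steady_state, dtype=float)
        if abs(pi.sum() - 1) > 1e-9 or np.any(pi <= 0) or np.any(pi >= 1):
            raise ValueError("steady-state components must lie in (0, 1) and sum to 1")


def _scale_proportion(p: float, pi: float) -> float:
    """Piecewise-linear rescaling mapping 0->0, pi->1/3, 1->1."""
    if p <= pi:
        return p / pi / 3.0
    return 1.0 + (p - 1.0) / (1.0 - pi) * (2.0 / 3.0)


def lineage_entropy(p, params: EntropyParams | None = None) -> float:
    """Rescaled Shannon entropy of a lineage composition, in [0, 1].

    Each state proportion is mapped piecewise-linearly so the steady-state
    composition scales to (1/3, 1/3, 1/3); the (non-renormalized) scaled
    triple is fed through −Σ P′ log3 P′. Equals 0 exactly at the vertices
    and 1 exactly at the steady state.
    """
    params = params or EntropyParams()
    p = _check_simplex(p)
    scaled = np.array(
        [_scale_proportion(float(pi_obs), pi_ss)
         for pi_obs, pi_ss in zip(p, params.steady_state)]
    )
    nz = scaled[scaled > 0]
    return float(-(nz * np.log(nz) / np.log(params.base)).sum())


def vector_field(
    proportions: pd.DataFrame,
    id_col: str = "barcode",
    bin_width: float = 0.1,
    embedding: str = "axis",
) -> pd.DataFrame:
    """Binned mean displacement field over all consecutive transitions.

    Each (lineage, transition) contributes its start position's bin one
    displacement vector, equally weighted across the four transitions. Bins
    report the mean displacement, number of contributing lineages, total
    cells (if a 'cells' column is present via per-row totals) and the number
    of entries that actually moved. Empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    timepoints = sorted(proportions["timepoint"].unique())
    wide = proportions.set_index([id_col, "timepoint"])
    entries = []
    for lin in proportions[id_col].unique():
        sub = wide.loc[lin]
        for k in range(len(timepoints) - 1):
            t0, t1 = timepoints[k], timepoints[k + 1]
            if t0 not in sub.index or t1 not in sub.index:
                continue
            c0 = ternary_coords(sub.loc[t0, list(STATES)].to_numpy(), embedding)
            c1 = ternary_coords(sub.loc[t1, list(STATES)].to_numpy(), embedding)
            cells = float(sub.loc[t0]["cells"]) if "cells" in sub.columns else np.nan
            entries.append(
                {
                    id_col: lin,
                    "bin_x": np.floor(c0[0] / bin_width) * bin_width,
                    "bin_y": np.floor(c0[1] / bin_width) * bin_width,
                    "dx": c1[0] - c0[0],
                    "dy": c1[1] - c0[1],
                    "cells": cells,
                }
            )
    df = pd.DataFrame(entries)
    if df.empty:
        return df
    moved = np.hypot(df["dx"], df["dy"]) > 1e-12
    df["moved"] = moved
    out = (
        df.groupby(["bin_x", "bin_y"])
        .agg(
            dx=("dx", "mean"),
            dy=("dy", "mean"),
            n_lineages=(id_col, "nunique"),
            n_cells=("cells", "sum"),
            n_transitioning=("moved", "sum"),
        )
        .reset_index()
    )
    return out


def differentiation_skew(
    cd24_cells: pd.DataFrame,
    motility_deciles: pd.DataFrame,
    id_col: str = "barcode",
    pseudocount: float = 1.0,
) -> dict:
    """Differentiation-fate skew of high-motility lineages.

    cd24_cells: tidy normalized cells with state in {CD24high, CD24low}.
    For every lineage detected in at least one class the log10 ratio of
    CD24high to CD24low cells (with a pseudocount added to each class) is
    computed; lineages are grouped by motility decile and the spread of
    log-ratios per decile — and for the pooled top-4 / bottom-4 decile
    groups — is compared against all lineages with a two-sided F test for
    equality of variances.
    """
    wide = cd24_cells.pivot_table(
        index=id_col, columns="state", values="cells", aggfunc="sum", fill_value=0.0
    )
    for col in ("CD24high", "CD24low"):
        if col not in wide.columns:
            wide[col] = 0.0
    wide = wide[(wide["CD24high"] > 0) | (wide["CD24low"] > 0)]
    ratios = np.log10((wide["CD24high"] + pseudocount) / (wide["CD24low"] + pseudocount))
    ratios.name = "log_ratio"
    merged = ratios.reset_index().merge(
        motility_deciles[[id_col, "decile"]], on=id_col, how="inner"
    )

    def f_test(sub: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
        if len(sub) < 2 or len(ref) < 2 or np.var(ref, ddof=1) == 0:
            return np.nan, np.nan
        f = np.var(sub, ddof=1) / np.var(ref, ddof=1)
        d1, d2 = len(sub) - 1, len(ref) - 1
        p = 2 * min(stats.f.sf(f, d1, d2), stats.f.cdf(f, d1, d2))
        return float(f), float(min(p, 1.0))

    all_ratios = merged["log_ratio"].to_numpy()
    per_decile = []
    for dec, grp in merged.groupby("decile"):
        f, p = f_test(grp["log_ratio"].to_numpy(), all_ratios)
        per_decile.append({"decile": dec, "n": len(grp), "F": f, "p_value": p})
    groups = {}
    for name, mask in (
        ("top4", merged["decile"] >= 7),
        ("bottom4", merged["decile"] <= 4),
    ):
        f, p = f_test(merged.loc[mask, "log_ratio"].to_numpy(), all_ratios)
        groups[name] = {"n": int(mask.sum()), "F": f, "p_value": p}
    return {
        "ratios": merged,
        "per_decile": pd.DataFrame(per_decile),
        "groups": groups,
    }
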
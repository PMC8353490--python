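"""Transition-matrix estimation and Markov-property testing.

The workhorse model is the linear map X M = Y between pre- and
post-transition state compositions. Estimators provided:

* population / pooled OLS fit ``M = (XᵀX)⁻¹XᵀY`` (unconstrained — the
  estimate need not be right stochastic and is deliberately not normalized);
* constrained fit with rows on the probability simplex (bounded least
  squares with row-sum-1 equality constraints), used for lineage-specific
  matrices that must be interpretable as probabilities;
* growth-birth-death decomposition: with U, V the pre-/post-transition cell
  numbers, G solves (U·M)G = V by least squares, and the per-transition net
  growth rate is the Hadamard quotient (e_i·M·G)_j / (e_i·M)_j.

Markov-property tests compare observed post-transition cell numbers with
those predicted by a fitted transition matrix via the chi-square test of
homogeneity, at the population level (percentage rows) and per lineage
(integer cell counts under the 10^6-per-timepoint renormalization), with
Benjamini-Hochberg correction across lineages within each transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .normalization import MARKOV_TEST_SCHEME, filter_complete_lineages, state_proportions
from .synthetic import STATES


@dataclass
class TransitionMatrix:
    matrix: np.ndarray
    constrained: bool = False
    degenerate: bool = False  # rank-deficient fit solved by pseudo-inverse
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.constrained:
            if np.any(self.matrix < -1e-9) or np.any(
                np.abs(self.matrix.sum(axis=1) - 1) > 1e-9
            ):
                raise ValueError("constrained matrix must be right stochastic")


@dataclass
class MarkovTestResult:
    lineage: object
    transition: tuple
    statistic: float
    df: int
    p_value: float
    adjusted_p: float = np.nan
    classification: str = "uninformative"
    n_categories: int = 0


def fit_transition_matrix(X: np.ndarray, Y: np.ndarray) -> TransitionMatrix:
    """Unconstrained OLS solution of X M = Y.

    Minimizes ‖Y − XM‖²; when XᵀX is singular the minimum-norm
    pseudo-inverse solution is returned and flagged degenerate.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("X and Y must be 2-D and of identical shape")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many observation rows as states")
    rank = np.linalg.matrix_rank(X)
    degenerate = rank < X.shape[1]
    M, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residual = float(np.linalg.norm(Y - X @ M))
    return TransitionMatrix(M, constrained=False, degenerate=degenerate, residual=residual)


def fit_constrained_matrix(X: np.ndarray, Y: np.ndarray) -> TransitionMatrix:
    """Least squares for X M = Y with M right stochastic.

    Entries are bounded to [0, 1] and each row sums to exactly 1; solved as
    a 9-variable SLSQP program with analytic gradient. Where a row of M is
    unidentifiable (e.g. its source state never occupied) the solution stays
    on the simplex and the fit is flagged degenerate.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (n, 3) arrays")
    degenerate = np.linalg.matrix_rank(X) < 3

    def objective(m: np.ndarray):
        M = m.reshape(3, 3)
        R = X @ M - Y
        return float((R * R).sum()), (2 * X.T @ R).ravel()

    constraints = [
        {
            "type": "eq",
            "fun": lambda m, i=i: m.reshape(3, 3)[i].sum() - 1.0,
            "jac": lambda m, i=i: np.eye(3)[i][:, None].repeat(3, 1).ravel(),
        }
        for i in range(3)
    ]
    x0 = np.full(9, 1.0 / 3.0)
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        bounds=[(0.0, 1.0)] * 9,
        constraints=constraints,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    M = res.x.reshape(3, 3)
    M = np.clip(M, 0.0, 1.0)
    M /= M.sum(axis=1, keepdims=True)
    residual = float(np.linalg.norm(Y - X @ M))
    return TransitionMatrix(M, constrained=True, degenerate=degenerate, residual=residual)


def _chi_square_row(observed: np.ndarray, expected: np.ndarray) -> tuple[float, int]:
    """Homogeneity statistic Σ(O−E)²/E over categories with positive support.

    Categories with non-positive expected or observed values are dropped and
    the degrees of freedom reduced accordingly (df = k − 1).
    """
    keep = (expected > 0) & (observed > 0)
    k = int(keep.sum())
    if k < 2:
        return np.nan, k - 1
    o, e = observed[keep], expected[keep]
    return float(((o - e) ** 2 / e).sum()), k - 1


def population_fit_test(X: np.ndarray, Y: np.ndarray) -> dict:
    """Population-level Markov check on FACS percentage rows.

    Fits M by OLS on the (timepoints × states) percentage matrices, predicts
    X′ = XM, and runs a per-row chi-square comparison of observed (Y) versus
    expected (X′) percentages with df = 2. The population is labeled
    Markovian when every row's p exceeds 0.05.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    scale = X.sum(axis=1).mean()
    if np.any(np.abs(X.sum(axis=1) - scale) > 0.05 * scale):
        raise ValueError("rows of X must share a common total (percentages)")
    fit = fit_transition_matrix(X, Y)
    expected = X @ fit.matrix
    rows = []
    for r in range(X.shape[0]):
        statistic, df = _chi_square_row(Y[r], expected[r])
        p = float(stats.chi2.sf(statistic, df)) if df >= 1 and np.isfinite(statistic) else np.nan
        rows.append({"row": r, "statistic": statistic, "df": df, "p_value": p})
    table = pd.DataFrame(rows)
    return {
        "fit": fit,
        "expected": expected,
        "tests": table,
        "markovian": bool((table["p_value"] > 0.05).all()),
    }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lineage_markov_test(
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    Mi: TransitionMatrix | np.ndarray,
    lineage: object = None,
    transition: tuple = (None, None),
) -> MarkovTestResult:
    """Chi-square homogeneity test of one lineage's transition a -> b.

    cells_a / cells_b are integer 3-vectors of the lineage's cell numbers
    under the 10^6-per-timepoint renormalization. Expected counts are
    N′_b = (x_a · Mi) × Σ cells_b with x_a the observed proportions at a.
    Categories with non-positive expected or observed cells are removed; a
    test with fewer than 2 usable categories is uninformative.
    """
    M = Mi.matrix if isinstance(Mi, TransitionMatrix) else np.asarray(Mi, dtype=float)
    cells_a = np.asarray(cells_a, dtype=float)
    cells_b = np.asarray(cells_b, dtype=float)
    total_a, total_b = cells_a.sum(), cells_b.sum()
    if total_a <= 0 or total_b <= 0:
        return MarkovTestResult(lineage, transition, np.nan, 0, np.nan)
    expected = (cells_a / total_a) @ M * total_b
    statistic, df = _chi_square_row(cells_b, expected)
    if df < 1 or not np.isfinite(statistic):
        return MarkovTestResult(lineage, transition, np.nan, max(df, 0), np.nan,
                                n_categories=df + 1)
    p = float(stats.chi2.sf(statistic, df))
    return MarkovTestResult(lineage, transition, statistic, df, p, n_categories=df + 1)


def classify_lineages(
    cell_table: pd.DataFrame,
    id_col: str = "lineage",
    alpha: float = 0.05,
    scheme: dict = MARKOV_TEST_SCHEME,
    constrained: bool = False,
) -> pd.DataFrame:
    """Per-lineage Markov-property classification over every transition.

    Expects a tidy cell table (id, timepoint, state, cells) under the
    *default* normalization (real-valued cells). The 10^6 renormalization
    with floor rounding is applied internally; lineages falling below one
    cell somewhere become untestable (attrition). For each retained lineage
    a lineage-specific Mi is fitted on its four transition rows, each
    transition is chi-square tested, and p-values are BH-corrected across
    lineages within each transition. Returns one row per (lineage,
    transition) with classification markovian / non_markovian /
    uninformative.
    """
    timepoints = sorted(cell_table["timepoint"].unique())
    # renormalize to the Markov-test totals with floor rounding
    pseudo_reads = cell_table.rename(columns={"cells": "reads"})
    from .normalization import normalize_counts  # local import to avoid cycle

    test_cells = normalize_counts(pseudo_reads, scheme=scheme, rounding="floor")
    retained_tbl, retained = filter_complete_lineages(test_cells, id_col=id_col)

    wide = retained_tbl.pivot_table(
        index=[id_col, "timepoint"], columns="state", values="cells",
        aggfunc="sum", fill_value=0.0,
    ).reindex(columns=list(STATES), fill_value=0.0)

    results: list[MarkovTestResult] = []
    untested = set(cell_table[id_col].unique()) - set(retained)
    for lin in retained:
        counts = np.vstack([wide.loc[(lin, t)].to_numpy() for t in timepoints])
        props = counts / counts.sum(axis=1, keepdims=True)
        Xi, Yi = props[:-1], props[1:]
        Mi = (
            fit_constrained_matrix(Xi, Yi) if constrained else fit_transition_matrix(Xi, Yi)
        )
        for k in range(len(timepoints) - 1):
            results.append(
                lineage_markov_test(
                    counts[k], counts[k + 1], Mi, lineage=lin,
                    transition=(timepoints[k], timepoints[k + 1]),
                )
            )
    for lin in sorted(untested):
        for k in range(len(timepoints) - 1):
            results.append(
                MarkovTestResult(lin, (timepoints[k], timepoints[k + 1]),
                                 np.nan, 0, np.nan)
            )

    df = pd.DataFrame(
        {
            id_col: [r.lineage for r in results],
            "transition": [f"{r.transition[0]}->{r.transition[1]}" for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    df["adjusted_p"] = np.nan
    for _, idx in df.groupby("transition").groups.items():
        sub = df.loc[idx]
        testable = sub["p_value"].notna()
        if testable.any():
            df.loc[sub.index[testable], "adjusted_p"] = bh_adjust(
                sub.loc[testable, "p_value"].to_numpy()
            )
    df["classification"] = "uninformative"
    tested = df["adjusted_p"].notna()
    df.loc[tested & (df["adjusted_p"] < alpha), "classification"] = "non_markovian"
    df.loc[tested & (df["adjusted_p"] >= alpha), "classification"] = "markovian"
    return df


def bootstrap_matrix_ci(
    X: np.ndarray,
    Y: np.ndarray,
    frac: float = 0.8,
    n_iter: int = 1000,
    seed: int = 0,
    replace: bool = True,
) -> dict:
    """Percentile bootstrap confidence intervals for the entries of M.

    Each iteration resamples ⌊frac·n⌋ observation rows (with replacement by
    default — see docs/methods.md for why the without-replacement variant
    undercovers) and refits the OLS matrix; reports per-entry 2.5/97.5
    percentiles.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 rows to bootstrap")
    m = int(np.floor(frac * n))
    rng = np.random.default_rng(seed)
    draws = np.empty((n_iter, 3, 3))
    for it in range(n_iter):
        idx = rng.choice(n, size=m, replace=replace)
        draws[it] = np.linalg.lstsq(X[idx], Y[idx], rcond=None)[0]
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    return {"lower": lo, "upper": hi, "draws": draws,
            "point": fit_transition_matrix(X, Y).matrix}


def fit_growth_matrix(
    U: np.ndarray,
    V: np.ndarray,
    M: TransitionMatrix | np.ndarray,
    literal: bool = False,
) -> TransitionMatrix:
    """Least-squares growth-birth-death factor G reconciling (U·M)G with V.

    U and V stack per-(lineage, transition) cell-number rows (pre and post).
    The default follows the per-lineage derivation U′G = V with U′ = U·M;
    ``literal=True`` instead solves U G = V directly.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape != V.shape or U.ndim != 2:
        raise ValueError("U and V must be matching 2-D arrays")
    if U.shape[0] < U.shape[1]:
        raise ValueError("underdetermined: fewer rows than unknown matrix rows")
    Mmat = M.matrix if isinstance(M, TransitionMatrix) else np.asarray(M, dtype=float)
    design = U if literal else U @ Mmat
    rank = np.linalg.matrix_rank(design)
    G, *_ = np.linalg.lstsq(design, V, rcond=None)
    return TransitionMatrix(
        G, constrained=False, degenerate=rank < design.shape[1],
        residual=float(np.linalg.norm(V - design @ G)),
    )


def growth_birth_death_rates(
    M: TransitionMatrix | np.ndarray, G: TransitionMatrix | np.ndarray
) -> np.ndarray:
    """Per-transition net growth rates: (e_i·M·G)_j / (e_i·M)_j.

    Rows are source states scaled to 100 cells; entries where the
    transition-only prediction is zero are undefined and reported as NaN.
    A rate above 1 means cells making transition i -> j net-expanded.
    """
    Mmat = M.matrix if isinstance(M, TransitionMatrix) else np.asarray(M, dtype=float)
    Gmat = G.matrix if isinstance(G, TransitionMatrix) else np.asarray(G, dtype=float)
    rates = np.full((3, 3), np.nan)
    for i in range(3):
        n = np.zeros(3)
        n[i] = 100.0
        transition_only = n @ Mmat
        with_growth = n @ Mmat @ Gmat
        ok = np.abs(transition_only) > 1e-12
        rates[i, ok] = with_growth[ok] / transition_only[ok]
    return rates


def stacked_transition_arrays(
    cell_table: pd.DataFrame,
    id_col: str = "lineage",
    value_col: str = "cells",
    as_proportions: bool = True,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack per-lineage rows over all consecutive transitions.

    Returns (X, Y, index) where row k of X/Y holds lineage index.lineage[k]
    at the earlier/later timepoint of index.transition[k]; proportions when
    as_proportions (pooled transition fit), raw cell numbers otherwise
    (growth fit inputs U, V).
    """
    timepoints = sorted(cell_table["timepoint"].unique())
    wide = cell_table.pivot_table(
        index=[id_col, "timepoint"], columns="state", values=value_col,
        aggfunc="sum", fill_value=0.0,
    ).reindex(columns=list(STATES), fill_value=0.0)
    X_rows, Y_rows, meta = [], [], []
    lineages = sorted({i for i, _ in wide.index})
    for lin in lineages:
        sub = wide.loc[lin].reindex(timepoints, fill_value=0.0).to_numpy()
        totals = sub.sum(axis=1)
        if np.any(totals <= 0):
            continue  # incomplete lineage
        vals = sub / totals[:, None] if as_proportions else sub
        for k in range(len(timepoints) - 1):
            X_rows.append(vals[k])
            Y_rows.append(vals[k + 1])
            meta.append({id_col: lin, "transition": f"{timepoints[k]}->{timepoints[k+1]}"})
    return np.array(X_rows), np.array(Y_rows), pd.DataFrame(meta)
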
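"""History dependence of lineage state sequences.

Each lineage is reduced to a length-5 sequence of plurality-vote states
(the state holding its largest cell count at each sampling day). Memory is
quantified by conditioning the final transition on histories of increasing
depth: under the Markov property,

    P(X_{n+1} = s | X_1 .. X_n) = P(X_{n+1} = s | X_n),

so conditional next-state distributions for two histories sharing the same
final state must agree. Pairs of history motifs are compared with Fisher's
exact test on the 2×k table of next-state counts (exact hypergeometric
enumeration; Monte Carlo fallback for large tables), with BH or Bonferroni
correction. The same machinery applies to binary high/low *motility*
sequences. Randomization nulls (motility reassignment between replicates,
read-count permutation) guard against library-preparation artifacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, lgamma

import numpy as np
import pandas as pd

from .markov import bh_adjust
from .synthetic import STATES


def plurality_state(cells, states: tuple = STATES) -> tuple[str, bool]:
    """State with the highest cell count; ties break to the lower state index.

    Returns (state, tie_flag). Rejects all-zero input.
    """
    c = np.asarray(cells, dtype=float)
    if c.sum() <= 0:
        raise ValueError("plurality vote undefined for an empty lineage")
    best = int(c.argmax())
    tie = bool((c == c[best]).sum() > 1)
    return states[best], tie


def state_sequences(
    cell_table: pd.DataFrame,
    id_col: str = "barcode",
    states: tuple = STATES,
    min_share: float | None = None,
) -> pd.DataFrame:
    """Plurality-vote state sequence per lineage (one column per timepoint).

    ``min_share`` optionally tightens the vote: the winning state must also
    hold at least that fraction of the lineage's cells, else the timepoint
    is recorded as missing and the lineage dropped (robustness check on the
    plurality criterion).
    """
    timepoints = sorted(cell_table["timepoint"].unique())
    wide = cell_table.pivot_table(
        index=[id_col, "timepoint"], columns="state", values="cells",
        aggfunc="sum", fill_value=0.0,
    ).reindex(columns=list(states), fill_value=0.0)
    rows = []
    for lin in sorted(cell_table[id_col].unique()):
        seq, ok = [], True
        for t in timepoints:
            if (lin, t) not in wide.index:
                ok = False
                break
            c = wide.loc[(lin, t)].to_numpy()
            if c.sum() <= 0:
                ok = False
                break
            state, _tie = plurality_state(c, states)
            if min_share is not None and c.max() / c.sum() < min_share:
                ok = False
                break
            seq.append(state)
        if ok:
            rows.append({id_col: lin, **{f"t{t}": s for t, s in zip(timepoints, seq)}})
    return pd.DataFrame(rows)


def _sequence_matrix(sequences: pd.DataFrame, id_col: str) -> list[tuple]:
    cols = [c for c in sequences.columns if c != id_col]
    return [tuple(row) for row in sequences[cols].to_numpy()]


def motif_conditional_probs(
    sequences: pd.DataFrame, depth: int, id_col: str = "barcode"
) -> pd.DataFrame:
    """Counts and conditional probabilities of the final state given the
    preceding ``depth`` states.

    Motifs are anchored at the end of the sequence (the last ``depth``
    states before the final timepoint), so a depth-k table marginalizes
    exactly onto the depth-(k−1) table. Depth 1 is the memoryless reference.
    """
    seqs = _sequence_matrix(sequences, id_col)
    if not seqs:
        return pd.DataFrame(columns=["motif", "next_state", "count", "probability"])
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must share one length")
    if not 1 <= depth <= length - 1:
        raise ValueError(f"depth must be in [1, {length - 1}]")
    counts: dict[tuple, dict[str, int]] = {}
    for s in seqs:
        motif, nxt = s[length - 1 - depth : length - 1], s[length - 1]
        bucket = counts.setdefault(motif, {})
        bucket[nxt] = bucket.get(nxt, 0) + 1
    rows = []
    for motif in sorted(counts):
        total = sum(counts[motif].values())
        for nxt, n in sorted(counts[motif].items()):
            rows.append(
                {
                    "motif": "|".join(str(m) for m in motif),
                    "next_state": nxt,
                    "count": n,
                    "probability": n / total,
                }
            )
    return pd.DataFrame(rows)


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a 2×k table given margins."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    num = sum(lgamma(r + 1) for r in row) + sum(lgamma(c + 1) for c in col)
    den = lgamma(n + 1) + sum(lgamma(v + 1) for v in table.ravel())
    return num - den


def fisher_exact_2xk(table: np.ndarray, n_mc: int = 100_000, seed: int = 0) -> float:
    """Exact Fisher p for a 2×k contingency table by full enumeration.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more likely than the observed one. Tables
    whose enumeration exceeds ~2×10^6 candidates fall back to Monte Carlo
    with ``n_mc`` draws (flag: returned p is then an estimate).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2×k table")
    if np.any(table < 0):
        raise ValueError("negative counts")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if row.min() == 0 or col.min() == 0:
        raise ValueError("degenerate table: empty row or column")
    k = table.shape[1]
    obs_logp = _log_table_prob(table)

    ranges = [range(0, min(row[0], col[j]) + 1) for j in range(k - 1)]
    n_candidates = int(np.prod([len(r) for r in ranges])) if k > 1 else 1
    if n_candidates <= 2_000_000:
        p = 0.0
        for first in itertools.product(*ranges):
            last = row[0] - sum(first)
            if last < 0 or last > col[k - 1]:
                continue
            top = np.array(list(first) + [last])
            bottom = col - top
            if np.any(bottom < 0):
                continue
            cand = np.vstack([top, bottom])
            lp = _log_table_prob(cand)
            if lp <= obs_logp + 1e-9:
                p += np.exp(lp)
        return float(min(p, 1.0))

    # Monte Carlo: permute pooled outcomes across the two history groups
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), col)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        top = np.bincount(pool[: row[0]], minlength=k)
        cand = np.vstack([top, col - top])
        if _log_table_prob(cand) <= obs_logp + 1e-9:
            hits += 1
    return float((hits + 1) / (n_mc + 1))


@dataclass
class FisherResult:
    motif_a: object
    motif_b: object
    table: np.ndarray
    p_value: float
    adjusted_p: float = np.nan


def history_fisher_tests(
    sequences: pd.DataFrame,
    depth: int,
    id_col: str = "barcode",
    correction: str = "bh",
) -> list[FisherResult]:
    """Fisher tests between history motifs sharing the final pre-transition state.

    For every pair of depth-``depth`` motifs whose last element matches, the
    2×k table of next-state counts is tested; motif pairs whose table has an
    empty row or column (the Fisher statistic undefined) are excluded, per
    the restriction to histories with lineages in all states at the final
    timepoint. ``correction`` is "bh" (state-sequence analysis) or
    "bonferroni" (motility-state analysis).
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    probs = motif_conditional_probs(sequences, depth, id_col)
    if probs.empty:
        return []
    pivot = probs.pivot_table(
        index="motif", columns="next_state", values="count", fill_value=0
    )
    motifs = list(pivot.index)
    results: list[FisherResult] = []
    for a, b in itertools.combinations(motifs, 2):
        # histories must share the final pre-transition state
        if a.split("|")[-1] != b.split("|")[-1]:
            continue
        tab = np.vstack([pivot.loc[a].to_numpy(), pivot.loc[b].to_numpy()]).astype(int)
        tab = tab[:, tab.sum(axis=0) > 0]  # next-states nobody reached carry no signal
        if tab.shape[1] < 2 or tab.sum(axis=1).min() == 0:
            continue
        p = fisher_exact_2xk(tab)
        results.append(FisherResult(a, b, tab, p))
    if results:
        raw = np.array([r.p_value for r in results])
        adj = bh_adjust(raw) if correction == "bh" else np.minimum(raw * len(raw), 1.0)
        for r, a_p in zip(results, adj):
            r.adjusted_p = float(a_p)
    return results


def motility_states(
    motility_tbl: pd.DataFrame,
    id_col: str = "barcode",
    threshold: str | float = "median",
) -> pd.DataFrame:
    """Binary high/low motility sequence per lineage (one element per transition).

    Default threshold is the per-transition median motility; a float applies
    one global cut. Rejects degenerate input where a transition's motilities
    are all identical (no cut can split them).
    """
    m_cols = [c for c in motility_tbl.columns if c.startswith("m_")]
    out = motility_tbl[[id_col]].copy()
    for c in m_cols:
        vals = motility_tbl[c].to_numpy()
        if np.allclose(vals, vals[0]):
            raise ValueError(f"degenerate motility in {c}: all values equal")
        cut = float(np.median(vals)) if threshold == "median" else float(threshold)
        out[c.replace("m_", "h_")] = np.where(vals > cut, "high", "low")
    return out


def motility_randomization_null(
    shared: pd.DataFrame,
    rep1_pool: np.ndarray,
    rep2_pool: np.ndarray,
    n_trials: int = 100_000,
    seed: int = 0,
) -> dict:
    """Null distribution of replicate motility correlation by random assignment.

    ``shared`` holds the observed percent motility of the lineages present
    in both replicates (columns rep1, rep2); the pools are each replicate's
    empirical per-transition motility values (percent). Per trial, every
    shared lineage is assigned a random draw from its replicate's pool, the
    log10 percent motilities are correlated, and the trial's Pearson r and
    R² recorded. Zero motilities are excluded pairwise under the log.
    Returns observed r plus per-trial null r and R² arrays.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    obs1 = shared["rep1"].to_numpy(dtype=float)
    obs2 = shared["rep2"].to_numpy(dtype=float)
    ok = (obs1 > 0) & (obs2 > 0)
    observed_r = float(np.corrcoef(np.log10(obs1[ok]), np.log10(obs2[ok]))[0, 1])

    rng = np.random.default_rng(seed)
    n = len(shared)
    p1 = np.asarray(rep1_pool, dtype=float)
    p2 = np.asarray(rep2_pool, dtype=float)
    p1, p2 = p1[p1 > 0], p2[p2 > 0]  # pairwise zero-exclusion applied up front
    l1, l2 = np.log10(p1), np.log10(p2)

    r_null = np.empty(n_trials)
    chunk = max(1, min(n_trials, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_trials:
        m = min(chunk, n_trials - done)
        a = l1[rng.integers(0, len(l1), size=(m, n))]
        b = l2[rng.integers(0, len(l2), size=(m, n))]
        a -= a.mean(axis=1, keepdims=True)
        b -= b.mean(axis=1, keepdims=True)
        num = (a * b).sum(axis=1)
        den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
        r_null[done : done + m] = num / den
        done += m
    return {
        "observed_r": observed_r,
        "null_r": r_null,
        "null_r2": r_null**2,
        "n_excluded_zero": int((~ok).sum()),
    }


def read_reassignment_null(
    counts: pd.DataFrame,
    seed: int,
    id_col: str = "barcode",
    identity: bool = False,
) -> pd.DataFrame:
    """Permute read counts across barcodes within each sample.

    Destroys any lineage-level structure while preserving every sample's
    read-count distribution; downstream motility correlations between early
    and late transitions must vanish on the permuted table. With
    ``identity=True`` the permutation is the identity (control).
    """
    rng = np.random.default_rng(seed)
    out = counts.copy()
    for _, grp in out.groupby(["timepoint", "state"]):
        vals = grp["reads"].to_numpy().copy()
        if not identity:
            rng.shuffle(vals)
        out.loc[grp.index, "reads"] = vals
    return out


def transition_motility_correlations(motility_tbl: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of per-transition motilities."""
    m_cols = [c for c in motility_tbl.columns if c.startswith("m_")]
    return motility_tbl[m_cols].corr(method="pearson")


def decision_tree_export(
    sequences: pd.DataFrame, id_col: str = "barcode"
) -> pd.DataFrame:
    """Edge list of the lineage state-flow tree across consecutive timepoints.

    One edge per (timepoint pair, source state, target state) with lineage
    counts and the proportion of the source node's lineages taking the edge
    (proportions out of each source node sum to 1).
    """
    if sequences.empty:
        raise ValueError("no sequences")
    cols = [c for c in sequences.columns if c != id_col]
    rows = []
    for k in range(len(cols) - 1):
        pair = sequences.groupby([cols[k], cols[k + 1]]).size()
        source_tot = sequences.groupby(cols[k]).size()
        for (a, b), n in pair.items():
            rows.append(
                {
                    "from_timepoint": cols[k],
                    "to_timepoint": cols[k + 1],
                    "from_state": a,
                    "to_state": b,
                    "n_lineages": int(n),
                    "proportion": n / source_tot[a],
                }
            )
    return pd.DataFrame(rows)


def decision_tree_graph(edges: pd.DataFrame):
    """Edge list -> networkx DiGraph (nodes are (timepoint, state) pairs)."""
    import networkx as nx

    g = nx.DiGraph()
    for _, e in edges.iterrows():
        u = (e["from_timepoint"], e["from_state"])
        v = (e["to_timepoint"], e["to_state"])
        g.add_edge(u, v, n_lineages=e["n_lineages"], proportion=e["proportion"])
    return g
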
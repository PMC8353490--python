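"""Synthetic clonal populations with known state-transition dynamics.

Generates barcoded lineages occupying three cell states over a 24-day time
course (sampling every 6 days), under one of three per-interval dynamics:

* ``markov`` — every cell independently draws its next state from the row of
  a fixed right-stochastic transition matrix;
* ``coordinated`` — with some probability per interval a lineage moves as a
  block: a single target state is drawn from the current plurality state's
  row and a Binomial fraction of every cell in the lineage moves there
  together (kin-coordinated, history-dependent behaviour);
* ``mixed`` — a fixed fraction of lineages is coordinated-capable, the rest
  are purely Markovian.

Cell counts making transition i->j are multiplied by ``growth_factors[i][j]``
(net growth-birth-death per transition type) with stochastic rounding, then
optionally thinned by FACS-style sorting, and finally emitted as amplicon
FASTQ so the whole downstream pipeline is testable without deposited data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon import (
    ALPHABET,
    AmpliconSpec,
    min_pairwise_hamming,
    random_distinct_sequences,
)

STATES = ("State1", "State2", "State3")
DEFAULT_TIMEPOINTS = (0, 6, 12, 18, 24)

#: Population steady state (long-run state proportions used throughout).
STEADY_STATE = (0.73, 0.15, 0.12)


def default_transition_matrix(persistence: float = 0.5) -> np.ndarray:
    """Right-stochastic matrix with stationary distribution STEADY_STATE.

    Each row is a convex mix of staying put and resampling from the steady
    state: ``M = a*I + (1-a)*1·pi``. Any persistence a in [0, 1) leaves pi
    invariant, so the generator's long-run behaviour matches the empirically
    motivated 0.73/0.15/0.12 composition.
    """
    pi = np.asarray(STEADY_STATE)
    return persistence * np.eye(3) + (1 - persistence) * np.ones((3, 1)) * pi


@dataclass
class SimulationConfig:
    """Stated world of the simulated experiment.

    Defaults mirror the real experiment's scale and composition: ~2,560
    analyzable lineages, cells sorted 90:5:5 across states, five sampling
    days (0, 6, 12, 18, 24), and half the culture sorted at each timepoint.
    """

    n_lineages: int = 2560
    initial_cells_per_lineage: int | tuple = 1000
    state_labels: tuple = STATES
    true_transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    growth_factors: np.ndarray = field(default_factory=lambda: np.ones((3, 3)))
    mode: str = "markov"
    coordination_prob: float = 0.5
    coordination_strength: float = 0.8
    mixed_fraction: float = 0.5
    initial_state_probs: tuple = (0.90, 0.05, 0.05)
    timepoints: tuple = DEFAULT_TIMEPOINTS
    sort_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_transition_matrix = np.asarray(self.true_transition_matrix, dtype=float)
        self.growth_factors = np.asarray(self.growth_factors, dtype=float)
        if self.n_lineages < 1:
            raise ValueError("need at least one lineage")
        M = self.true_transition_matrix
        if M.shape != (3, 3) or np.any(M < 0) or np.any(np.abs(M.sum(axis=1) - 1) > 1e-12):
            raise ValueError("true_transition_matrix must be 3x3 right stochastic")
        if self.growth_factors.shape != (3, 3) or np.any(self.growth_factors <= 0):
            raise ValueError("growth_factors must be 3x3 and strictly positive")
        if self.mode not in ("markov", "coordinated", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("coordination_prob", "coordination_strength", "mixed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 < self.sort_fraction <= 1.0:
            raise ValueError("sort_fraction outside (0, 1]")
        if abs(sum(self.initial_state_probs) - 1) > 1e-9:
            raise ValueError("initial_state_probs must sum to 1")
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Floor plus Bernoulli on the fractional part: unbiased at small counts."""
    f = np.floor(x)
    return (f + (rng.random(x.shape) < (x - f))).astype(np.int64)


def _markov_step(
    counts: np.ndarray, M: np.ndarray, growth: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One per-cell multinomial interval for an (n, 3) count matrix."""
    new = np.zeros_like(counts)
    for i in range(3):
        moved = rng.multinomial(counts[:, i], M[i])  # (n, 3) cells leaving state i
        new += _stochastic_round(moved * growth[i], rng)
    return new


def _coordinated_step(
    counts: np.ndarray,
    M: np.ndarray,
    growth: np.ndarray,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Block move: one target per lineage, a Binomial(strength) fraction follows."""
    n = counts.shape[0]
    plurality = counts.argmax(axis=1)  # ties break to the lower state index
    # draw each lineage's target state from its plurality state's row of M
    rows = M[plurality]
    target = (rng.random(n)[:, None] > rows.cumsum(axis=1)).sum(axis=1)
    target = np.minimum(target, 2)
    movers = rng.binomial(counts, strength)
    stayers = counts - movers
    new = np.zeros_like(counts)
    idx = np.arange(n)
    for i in range(3):
        new[:, i] += _stochastic_round(stayers[:, i] * growth[i, i], rng)
        new[idx, target] += _stochastic_round(movers[:, i] * growth[i, target], rng)
    return new


def simulate_lineages(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the full time course; returns a tidy truth table.

    Output columns: lineage, timepoint, state, cells (integer counts of the
    *cultured* population — sorting/sampling is a separate, later step).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lineages
    if isinstance(config.initial_cells_per_lineage, int):
        sizes = np.full(n, config.initial_cells_per_lineage, dtype=np.int64)
    else:  # ("lognormal", mean_cells, sigma) spec for skewed clone sizes
        kind, mean_cells, sigma = config.initial_cells_per_lineage
        if kind != "lognormal":
            raise ValueError(f"unknown size distribution {kind!r}")
        mu = np.log(mean_cells) - sigma**2 / 2
        sizes = np.maximum(1, np.rint(rng.lognormal(mu, sigma, size=n))).astype(np.int64)
    counts = rng.multinomial(sizes, config.initial_state_probs)

    if config.mode == "markov":
        coord_capable = np.zeros(n, dtype=bool)
    elif config.mode == "coordinated":
        coord_capable = np.ones(n, dtype=bool)
    else:
        coord_capable = rng.random(n) < config.mixed_fraction

    M, growth = config.true_transition_matrix, config.growth_factors
    frames = [counts.copy()]
    for _ in config.timepoints[1:]:
        coord_now = coord_capable & (rng.random(n) < config.coordination_prob)
        new = np.empty_like(counts)
        if (~coord_now).any():
            new[~coord_now] = _markov_step(counts[~coord_now], M, growth, rng)
        if coord_now.any():
            new[coord_now] = _coordinated_step(
                counts[coord_now], M, growth, config.coordination_strength, rng
            )
        counts = new
        frames.append(counts.copy())

    records = []
    for t, frame in zip(config.timepoints, frames):
        for s, state in enumerate(config.state_labels):
            records.append(
                pd.DataFrame(
                    {
                        "lineage": np.arange(n),
                        "timepoint": t,
                        "state": state,
                        "cells": frame[:, s],
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


def sort_and_sample(truth: pd.DataFrame, sort_fraction: float, seed: int) -> pd.DataFrame:
    """Binomial thinning of every (lineage, timepoint, state) cell count.

    Models FACS sorting of a fraction of the culture; with sort_fraction 1
    the table is returned unchanged (aside from a copy).
    """
    if not 0.0 < sort_fraction <= 1.0:
        raise ValueError("sort_fraction outside (0, 1]")
    out = truth.copy()
    if sort_fraction == 1.0:
        return out
    rng = np.random.default_rng(seed)
    out["cells"] = rng.binomial(out["cells"].to_numpy(), sort_fraction)
    return out


def assign_barcodes(
    n_lineages: int, rng: np.random.Generator, min_dist: int = 7
) -> dict[int, str]:
    """One 30-nt barcode per lineage with pairwise Hamming distance >= 7,
    so Hamming-<6 collapsing can never merge two distinct lineages."""
    seqs = random_distinct_sequences(n_lineages, 30, min_dist, rng)
    return dict(enumerate(seqs))


def assign_sample_indices(
    samples: Sequence[tuple], rng: np.random.Generator, min_dist: int = 3
) -> dict[str, tuple]:
    """Distinct 10-nt index per sample label, pairwise Hamming >= 3 so the
    <2-mismatch demultiplexing rule is unambiguous."""
    seqs = random_distinct_sequences(len(samples), 10, min_dist, rng)
    return dict(zip(seqs, samples))


def emit_fastq(
    truth_at_t: pd.DataFrame,
    spec: AmpliconSpec,
    index_map: dict[str, tuple],
    barcode_map: dict[int, str],
    out_dir: str,
    seed: int,
) -> dict[tuple, str]:
    """Write one FASTQ per (timepoint, state) sample for one timepoint's counts.

    Reads are the 129-nt barcode+constant1+index+constant2 concatenation with
    independent per-base substitution errors and Phred+33 qualities from the
    spec's quality model. Returns {sample label: fastq path}.
    """
    sample_to_index = {v: k for k, v in index_map.items()}
    if len(sample_to_index) != len(index_map):
        raise ValueError("duplicate sample labels in index_map")
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes) or (
        len(barcodes) > 1 and min_pairwise_hamming(barcodes) < 7
    ):
        raise ValueError("barcode collision under the Hamming-7 distance floor")

    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    alpha = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    paths: dict[tuple, str] = {}

    for (t, state), grp in truth_at_t.groupby(["timepoint", "state"], sort=True):
        sample = (t, state)
        if sample not in sample_to_index:
            raise KeyError(f"no sample index assigned for {sample}")
        index_seq = sample_to_index[sample]
        path = os.path.join(out_dir, f"d{t}_{state}.fastq")
        paths[sample] = path
        with open(path, "w") as fh:
            for _, row in grp.sort_values("lineage").iterrows():
                n_reads = int(np.rint(spec.reads_per_cell * row["cells"]))
                if n_reads == 0:
                    continue
                template = barcode_map[int(row["lineage"])] + spec.constant1 + index_seq + spec.constant2
                base = np.frombuffer(template.encode(), dtype=np.uint8)
                reads = np.tile(base, (n_reads, 1))
                if spec.per_base_error_rate > 0:
                    err = rng.random(reads.shape) < spec.per_base_error_rate
                    # substitute with one of the three other bases
                    shift = rng.integers(1, 4, size=reads.shape)
                    cur = np.searchsorted(alpha, reads)
                    reads = np.where(err, alpha[(cur + shift) % 4], reads)
                quals = spec.quality_model(n_reads, reads.shape[1], rng) + 33
                qual_bytes = quals.astype(np.uint8)
                for k in range(n_reads):
                    fh.write(
                        f"@L{int(row['lineage'])}_d{t}_{state}_{k}\n"
                        f"{reads[k].tobytes().decode()}\n+\n"
                        f"{qual_bytes[k].tobytes().decode('latin-1')}\n"
                    )
    return paths


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
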
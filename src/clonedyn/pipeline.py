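"""End-to-end orchestration: simulate -> extract -> normalize -> analyze.

Stages are toggled from a config mapping (YAML on disk); every stage writes
TSV/JSON outputs into the output directory and logs its row counts and
seeds into a manifest. All randomness flows from named seeds in the config,
so re-running an identical config is byte-identical for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from . import barcode_io, dynamics, history, markov, normalization, synthetic
from .amplicon import AmpliconSpec


DEFAULT_CONFIG = {
    "stages": ["simulate", "extract", "normalize", "markov", "dynamics", "history"],
    "out_dir": "clonedyn_out",
    "seeds": {"simulate": 1, "sort": 2, "fastq": 3, "barcodes": 4},
    "simulate": {"n_lineages": 200, "initial_cells_per_lineage": 500, "mode": "markov"},
    "amplicon": {"per_base_error_rate": 0.0, "reads_per_cell": 1.0},
    "normalize": {"scheme": "default"},
    "alpha": 0.05,
}

SCHEMES = {
    "default": normalization.DEFAULT_SCHEME,
    "markov_test": normalization.MARKOV_TEST_SCHEME,
    "cd24": normalization.CD24_SCHEME,
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = {**DEFAULT_CONFIG, **(cfg or {})}
    merged["seeds"] = {**DEFAULT_CONFIG["seeds"], **merged.get("seeds", {})}
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in order; returns the manifest."""
    stages = list(config.get("stages", []))
    out_dir = config.get("out_dir", "clonedyn_out")
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seeds": config.get("seeds", {}),
        "stages": {},
    }
    if not stages:
        warnings.warn("no stages enabled; writing an empty manifest")

    ctx: dict = {}
    for stage in stages:
        runner = _STAGES.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            manifest["stages"][stage] = runner(config, ctx, out_dir)
        except FileNotFoundError as err:
            raise FileNotFoundError(f"stage {stage!r}: {err}") from err

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _stage_simulate(config: dict, ctx: dict, out_dir: str) -> dict:
    sim_cfg = synthetic.SimulationConfig(
        seed=config["seeds"]["simulate"], **config.get("simulate", {})
    )
    truth = synthetic.simulate_lineages(sim_cfg)
    sorted_truth = synthetic.sort_and_sample(
        truth, sim_cfg.sort_fraction, config["seeds"]["sort"]
    )
    synthetic.write_truth_table(truth, os.path.join(out_dir, "truth.tsv"))
    synthetic.write_truth_table(sorted_truth, os.path.join(out_dir, "truth_sorted.tsv"))

    rng = np.random.default_rng(config["seeds"]["barcodes"])
    barcode_map = synthetic.assign_barcodes(sim_cfg.n_lineages, rng)
    samples = [
        (t, s) for t in sim_cfg.timepoints for s in sim_cfg.state_labels
    ]
    index_map = synthetic.assign_sample_indices(samples, rng)
    barcode_io.SampleIndexSet(index_map).to_tsv(os.path.join(out_dir, "indices.tsv"))
    pd.DataFrame(
        [{"lineage": k, "barcode": v} for k, v in barcode_map.items()]
    ).to_csv(os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False)

    spec = AmpliconSpec(**config.get("amplicon", {}))
    fastq_dir = os.path.join(out_dir, "fastq")
    paths = synthetic.emit_fastq(
        sorted_truth, spec, index_map, barcode_map, fastq_dir,
        config["seeds"]["fastq"],
    )
    ctx.update(
        truth=truth, sorted_truth=sorted_truth, barcode_map=barcode_map,
        index_map=index_map, spec=spec, fastq_paths=sorted(paths.values()),
    )
    return {
        "n_lineages": sim_cfg.n_lineages,
        "timepoints": list(sim_cfg.timepoints),
        "n_fastq": len(paths),
        "seed": sim_cfg.seed,
    }


def _stage_extract(config: dict, ctx: dict, out_dir: str) -> dict:
    fastq_paths = ctx.get("fastq_paths") or config.get("fastq")
    if not fastq_paths:
        raise FileNotFoundError("no FASTQ inputs (run the simulate stage or set 'fastq')")
    if "index_map" in ctx:
        indices = barcode_io.SampleIndexSet(ctx["index_map"])
    else:
        indices = barcode_io.SampleIndexSet.from_tsv(config["indices"])
    spec = ctx.get("spec") or AmpliconSpec(**config.get("amplicon", {}))
    counts, qc = barcode_io.extract_counts(fastq_paths, indices, spec)
    counts.to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t", index=False)
    barcode_io.write_qc_report(qc, os.path.join(out_dir, "qc.json"))
    ctx["counts"] = counts
    return {"reads": qc["total_reads"], "passed": qc["passed"],
            "n_barcodes": counts["barcode"].nunique() if not counts.empty else 0}


def _stage_normalize(config: dict, ctx: dict, out_dir: str) -> dict:
    counts = ctx.get("counts")
    if counts is None:
        path = config.get("counts")
        if not path:
            raise FileNotFoundError("no counts table (run extract or set 'counts')")
        counts = pd.read_csv(path, sep="\t")
    scheme = SCHEMES[config.get("normalize", {}).get("scheme", "default")]
    cells = normalization.normalize_counts(counts, scheme=scheme)
    cells, retained = normalization.filter_complete_lineages(cells)
    cells.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)
    ctx["cells"] = cells
    ctx["proportions"] = normalization.state_proportions(cells)
    ctx["proportions"].to_csv(
        os.path.join(out_dir, "proportions.tsv"), sep="\t", index=False
    )
    return {"n_complete_lineages": len(retained), "rows": len(cells)}


def _stage_markov(config: dict, ctx: dict, out_dir: str) -> dict:
    cells = _require(ctx, "cells")
    X, Y, meta = markov.stacked_transition_arrays(cells, id_col="barcode")
    fit = markov.fit_transition_matrix(X, Y)
    np.savetxt(os.path.join(out_dir, "pooled_M.tsv"), fit.matrix, delimiter="\t")
    classes = markov.classify_lineages(cells, id_col="barcode",
                                       alpha=config.get("alpha", 0.05))
    classes.to_csv(os.path.join(out_dir, "markov_tests.tsv"), sep="\t", index=False)
    U, V, _ = markov.stacked_transition_arrays(cells, id_col="barcode",
                                               as_proportions=False)
    G = markov.fit_growth_matrix(U, V, fit)
    rates = markov.growth_birth_death_rates(fit, G)
    np.savetxt(os.path.join(out_dir, "growth_G.tsv"), G.matrix, delimiter="\t")
    np.savetxt(os.path.join(out_dir, "growth_rates.tsv"), rates, delimiter="\t")
    ctx.update(pooled_fit=fit, markov_classes=classes)
    frac = (
        classes[classes["classification"] != "uninformative"]["classification"]
        .eq("non_markovian").mean()
        if not classes.empty else np.nan
    )
    return {"rows_fit": int(X.shape[0]), "non_markovian_fraction": float(frac)}


def _stage_dynamics(config: dict, ctx: dict, out_dir: str) -> dict:
    props = _require(ctx, "proportions")
    mot = dynamics.motility_table(props, id_col="barcode")
    mot.to_csv(os.path.join(out_dir, "motility.tsv"), sep="\t", index=False)
    props = props.copy()
    props["entropy"] = [
        dynamics.lineage_entropy(row) for row in props[list(synthetic.STATES)].to_numpy()
    ]
    props.to_csv(os.path.join(out_dir, "entropy.tsv"), sep="\t", index=False)
    field = dynamics.vector_field(props, id_col="barcode")
    field.to_csv(os.path.join(out_dir, "vector_field.tsv"), sep="\t", index=False)
    ctx["motility"] = mot
    return {"n_lineages": len(mot), "n_bins": len(field)}


def _stage_history(config: dict, ctx: dict, out_dir: str) -> dict:
    cells = _require(ctx, "cells")
    seqs = history.state_sequences(cells, id_col="barcode")
    seqs.to_csv(os.path.join(out_dir, "sequences.tsv"), sep="\t", index=False)
    edges = history.decision_tree_export(seqs, id_col="barcode")
    edges.to_csv(os.path.join(out_dir, "decision_tree.tsv"), sep="\t", index=False)
    n_tp = len(seqs.columns) - 1
    depth = min(config.get("history_depth", n_tp - 1), n_tp - 1)
    motifs = history.motif_conditional_probs(seqs, depth, id_col="barcode")
    motifs.to_csv(os.path.join(out_dir, "motifs.tsv"), sep="\t", index=False)
    fisher = history.history_fisher_tests(
        seqs, depth, id_col="barcode", correction=config.get("correction", "bh")
    )
    pd.DataFrame(
        [
            {
                "motif_a": r.motif_a, "motif_b": r.motif_b,
                "p_value": r.p_value, "adjusted_p": r.adjusted_p,
            }
            for r in fisher
        ]
    ).to_csv(os.path.join(out_dir, "fisher_tests.tsv"), sep="\t", index=False)
    return {"n_sequences": len(seqs), "n_motifs": motifs["motif"].nunique()
            if not motifs.empty else 0, "n_fisher_pairs": len(fisher)}


def _require(ctx: dict, key: str):
    if key not in ctx:
        raise FileNotFoundError(f"missing upstream output {key!r}")
    return ctx[key]


_STAGES = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "normalize": _stage_normalize,
    "markov": _stage_markov,
    "dynamics": _stage_dynamics,
    "history": _stage_history,
}
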
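"""Amplicon FASTQ processing: quality filtering, demultiplexing, collapsing.

Every read must pass four criteria before it contributes a count:

1. the summed Phred quality over the 30-base barcode region exceeds 80% of
   the maximum (0.8 × 40 × 30 = 960, strict inequality);
2. Hamming distance to constant region 1 (bases 31–95) is below 6;
3. Hamming distance to constant region 2 (terminal 24 bases) is below 3;
4. the 10-base index segment is within Hamming distance 1 of exactly the
   sample indices (distance < 2), which also assigns the read to a sample.

Barcodes surviving the filter are collapsed when less than 6 mismatches
apart, by abundance-ranked greedy centroid clustering on the pooled table so
a barcode maps to the same centroid in every sample.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .amplicon import (
    BARCODE_SLICE,
    CONSTANT1_SLICE,
    CONSTANT2_SLICE,
    INDEX_SLICE,
    AmpliconSpec,
    hamming,
)

#: strict threshold on the summed barcode-region Phred score (80% of 1200)
BARCODE_QUALITY_FLOOR = int(0.8 * 40 * 30)


@dataclass
class FilterResult:
    passed: bool
    reason: str | None  # None when passed
    sample: tuple | None
    barcode: str | None


class SampleIndexSet:
    """Map from 10-nt index sequences to sample labels.

    Indices must be unique and pairwise Hamming distance >= 3 so that the
    <2-mismatch assignment rule can never be ambiguous.
    """

    def __init__(self, index_to_sample: dict[str, tuple]):
        seqs = list(index_to_sample)
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate index sequences")
        lengths = {len(s) for s in seqs}
        if lengths and lengths != {10}:
            raise ValueError("sample indices must be 10 nt")
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                if hamming(a, b) < 3:
                    raise ValueError(f"indices {a} and {b} closer than Hamming 3")
        self.index_to_sample = dict(index_to_sample)

    def assign(self, observed: str) -> tuple | None:
        """Sample whose index is < 2 mismatches from the observed segment."""
        for seq, sample in self.index_to_sample.items():
            if hamming(observed, seq) < 2:
                return sample
        return None

    @classmethod
    def from_tsv(cls, path: str) -> "SampleIndexSet":
        df = pd.read_csv(path, sep="\t", dtype={"index": str})
        return cls(
            {
                row["index"]: (row["timepoint"], row["state"])
                for _, row in df.iterrows()
            }
        )

    def to_tsv(self, path: str) -> None:
        rows = [
            {"index": seq, "timepoint": s[0], "state": s[1]}
            for seq, s in self.index_to_sample.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def quality_filter_read(
    sequence: str,
    phred: np.ndarray | list[int],
    spec: AmpliconSpec,
    indices: SampleIndexSet,
) -> FilterResult:
    """Apply the four read criteria; on pass return sample label and barcode."""
    if len(sequence) < spec.read_length:
        return FilterResult(False, "truncated", None, None)
    phred = np.asarray(phred)
    if int(phred[BARCODE_SLICE].sum()) <= BARCODE_QUALITY_FLOOR:
        return FilterResult(False, "barcode_quality", None, None)
    if hamming(sequence[CONSTANT1_SLICE], spec.constant1) >= 6:
        return FilterResult(False, "constant1", None, None)
    if hamming(sequence[CONSTANT2_SLICE], spec.constant2) >= 3:
        return FilterResult(False, "constant2", None, None)
    sample = indices.assign(sequence[INDEX_SLICE])
    if sample is None:
        return FilterResult(False, "index", None, None)
    return FilterResult(True, None, sample, sequence[BARCODE_SLICE])


def _open_maybe_gzip(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def collapse_barcodes(counts: pd.DataFrame) -> pd.DataFrame:
    """Merge barcodes less than 6 mismatches apart into abundance centroids.

    Greedy clustering on the pooled (all-sample) table: barcodes are visited
    in descending total-read order; a barcode within Hamming distance <= 5 of
    an existing centroid merges into it, otherwise it founds a new centroid.
    Per-sample read totals are conserved.
    """
    if counts.empty:
        return counts.copy()
    lengths = counts["barcode"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError("mixed-length barcodes")

    pooled = (
        counts.groupby("barcode", sort=False)["reads"]
        .sum()
        .sort_values(ascending=False, kind="stable")
    )
    order = list(pooled.index)
    length = int(lengths[0])
    centroid_mat = np.empty((0, length), dtype=np.uint8)
    centroids: list[str] = []
    mapping: dict[str, str] = {}
    for bc in order:
        vec = np.frombuffer(bc.encode(), dtype=np.uint8)
        if centroid_mat.size:
            d = (centroid_mat != vec).sum(axis=1)
            j = int(d.argmin())
            if d[j] <= 5:
                mapping[bc] = centroids[j]
                continue
        mapping[bc] = bc
        centroids.append(bc)
        centroid_mat = np.vstack([centroid_mat, vec])

    out = counts.copy()
    out["barcode"] = out["barcode"].map(mapping)
    keys = [c for c in ("timepoint", "state") if c in out.columns]
    return out.groupby(keys + ["barcode"], as_index=False)["reads"].sum()


def extract_counts(
    fastq_paths: list[str],
    indices: SampleIndexSet,
    spec: AmpliconSpec,
    collapse: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """FASTQ files -> collapsed BarcodeCountTable + per-criterion QC report.

    The count table is tidy: columns timepoint, state, barcode, reads. The QC
    report gives total reads and attrition per criterion, overall and per file.
    """
    tallies: dict[tuple, dict[str, int]] = {}
    qc: dict = {"files": {}, "total_reads": 0, "passed": 0, "failed": {}}
    for path in fastq_paths:
        file_qc = {"reads": 0, "passed": 0, "failed": {}}
        with _open_maybe_gzip(path) as fh:
            for _title, seq, qual in FastqGeneralIterator(fh):
                file_qc["reads"] += 1
                phred = np.frombuffer(qual.encode("latin-1"), dtype=np.uint8).astype(int) - 33
                res = quality_filter_read(seq, phred, spec, indices)
                if res.passed:
                    file_qc["passed"] += 1
                    bucket = tallies.setdefault(res.sample, {})
                    bucket[res.barcode] = bucket.get(res.barcode, 0) + 1
                else:
                    file_qc["failed"][res.reason] = file_qc["failed"].get(res.reason, 0) + 1
        qc["files"][path] = file_qc
        qc["total_reads"] += file_qc["reads"]
        qc["passed"] += file_qc["passed"]
        for reason, n in file_qc["failed"].items():
            qc["failed"][reason] = qc["failed"].get(reason, 0) + n

    rows = [
        {"timepoint": sample[0], "state": sample[1], "barcode": bc, "reads": n}
        for sample, bucket in tallies.items()
        for bc, n in bucket.items()
    ]
    table = pd.DataFrame(rows, columns=["timepoint", "state", "barcode", "reads"])
    if table.empty:
        qc["warning"] = "no reads passed the filter"
        return table, qc
    if collapse:
        table = collapse_barcodes(table)
    return table.sort_values(["timepoint", "state", "barcode"]).reset_index(drop=True), qc


def base_frequency_qc(barcodes: list[str], weights: list[float] | None = None) -> pd.DataFrame:
    """Weighted per-position nucleotide frequency table (4 rows x 30 columns).

    Used to confirm that high-motility lineages' barcodes show no positional
    base skew (an amplification-artifact check); columns sum to 1.
    """
    if not barcodes:
        raise ValueError("empty barcode set")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must share one length")
    length = lengths.pop()
    w = np.ones(len(barcodes)) if weights is None else np.asarray(weights, dtype=float)
    mat = np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(len(barcodes), length)
    freqs = np.zeros((4, length))
    for i, base in enumerate(b"ACGT"):
        freqs[i] = ((mat == base) * w[:, None]).sum(axis=0)
    freqs /= freqs.sum(axis=0, keepdims=True)
    return pd.DataFrame(freqs, index=list("ACGT"), columns=range(1, length + 1))


def write_qc_report(qc: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, default=str)
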
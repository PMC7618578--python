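"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals are 0-based, half-open (BED convention). Junction
tables and sparse matrices are tab-separated text; FASTQ may be plain or
gzip-compressed (detected by the ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from typing import Iterable, Iterator

import numpy as np


# ---------------------------------------------------------------------------
# sequence formats


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None and line:
                out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality) triples as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header.rstrip("\n")[1:].split()[0], seq, qual


# ---------------------------------------------------------------------------
# interval formats


def write_bed(path, intervals: Iterable[tuple]) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) rows."""
    with _open_text(path, "wt") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            row = [f[0], int(f[1]), int(f[2])] + f[3:]
            rows.append(tuple(row))
    return rows


def write_bedgraph(path, chrom: str, values: np.ndarray, start: int = 0) -> None:
    """Write a per-bp profile, run-length collapsing equal adjacent values."""
    values = np.asarray(values, dtype=float)
    with _open_text(path, "wt") as fh:
        if values.size == 0:
            return
        run_start = 0
        for i in range(1, values.size + 1):
            if i == values.size or values[i] != values[run_start]:
                v = values[run_start]
                fh.write(f"{chrom}\t{start + run_start}\t{start + i}\t{v:g}\n")
                run_start = i


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")
            rows.append((c, int(s), int(e), float(v)))
    return rows


def bedgraph_to_profile(rows, length: int, chrom: str | None = None) -> np.ndarray:
    prof = np.zeros(length)
    for c, s, e, v in rows:
        if chrom is not None and c != chrom:
            continue
        prof[s:e] = v
    return prof


# ---------------------------------------------------------------------------
# matrix formats


def write_dense_matrix(path, matrix: np.ndarray, header: dict | None = None) -> None:
    with _open_text(path, "wt") as fh:
        if header:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        np.savetxt(fh, np.asarray(matrix), fmt="%.6g", delimiter="\t")


def read_dense_matrix(path) -> tuple[np.ndarray, dict]:
    header: dict = {}
    with _open_text(path) as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("#"):
            header = json.loads(first[1:])
        else:
            fh.seek(pos)
        mat = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return mat, header


def write_sparse_triplets(path, matrix: np.ndarray, header: dict | None = None) -> None:
    """Write nonzero entries as (row, col, count) rows; supports an extra
    leading channel axis (4, n, m) written as (channel, row, col, count)."""
    arr = np.asarray(matrix)
    with _open_text(path, "wt") as fh:
        if header:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        idx = np.nonzero(arr)
        for coords in zip(*idx):
            val = arr[coords]
            fh.write("\t".join(str(c) for c in coords) + f"\t{val:g}\n")


def read_sparse_triplets(path, shape: tuple[int, ...] | None = None) -> tuple[np.ndarray, dict]:
    header: dict = {}
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                header = json.loads(line[1:])
                continue
            if line:
                rows.append(line.split("\t"))
    if shape is None:
        shape = tuple(header["shape"])
    arr = np.zeros(shape)
    for r in rows:
        arr[tuple(int(x) for x in r[:-1])] = float(r[-1])
    return arr, header


# ---------------------------------------------------------------------------
# run manifests

__version__ = "0.1.0"


def write_manifest(path, command: str, params: dict, inputs: Iterable[str] = ()) -> None:
    """Machine-readable record of a pipeline invocation."""
    checksums = {}
    for p in inputs:
        if p and os.path.exists(p):
            with open(p, "rb") as fh:
                checksums[str(p)] = hashlib.sha256(fh.read()).hexdigest()[:16]
    manifest = {
        "command": command,
        "version": __version__,
        "parameters": {k: v for k, v in params.items()},
        "input_checksums": checksums,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
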
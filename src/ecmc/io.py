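"""Delimited-text I/O for matrices, kernels and label vectors.

Matrices travel as TSV with an optional header row of sample IDs. Values
are written with 17 significant digits so kernels round-trip bit-exactly
through text. Labels are two-column TSV (sample ID, cluster).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_matrix", "read_matrix", "write_labels", "read_labels"]


def write_matrix(path, M: np.ndarray, sample_ids: list[str] | None = None) -> None:
    M = np.asarray(M, dtype=float)
    path = Path(path)
    with path.open("w") as fh:
        if sample_ids is not None:
            if len(sample_ids) != M.shape[1]:
                raise ValueError("header length does not match column count")
            fh.write("\t".join(map(str, sample_ids)) + "\n")
        for row in M:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def read_matrix(path, header: str = "auto") -> tuple[np.ndarray, list[str] | None]:
    """Read a TSV matrix; returns (matrix, sample_ids or None).

    ``header="auto"`` treats the first row as sample IDs when it is not
    fully numeric.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.open() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    ids = None
    first = lines[0].split("\t")
    has_header = header is True or header == "yes"
    if header == "auto":
        try:
            [float(x) for x in first]
        except ValueError:
            has_header = True
    if has_header:
        ids = first
        lines = lines[1:]
    try:
        M = np.array([[float(x) for x in ln.split("\t")] for ln in lines])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix entry ({exc})") from None
    if not np.isfinite(M).all():
        raise ValueError(f"{path}: non-finite matrix entries")
    if ids is not None and len(ids) != M.shape[1]:
        raise ValueError(f"{path}: header length != column count")
    return M, ids


def write_labels(path, labels, sample_ids: list[str] | None = None) -> None:
    labels = np.asarray(labels).ravel()
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(labels.size)]
    with Path(path).open("w") as fh:
        for sid, lab in zip(sample_ids, labels):
            fh.write(f"{sid}\t{int(lab)}\n")


def read_labels(path) -> tuple[np.ndarray, list[str]]:
    ids, labels = [], []
    for ln in Path(path).open():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: expected two columns, got {len(parts)}")
        ids.append(parts[0])
        labels.append(int(parts[1]))
    if not labels:
        raise ValueError(f"{path}: empty label file")
    return np.array(labels), ids
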
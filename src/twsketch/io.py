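"""Matrix readers and writers shared by the command-line tools.

Two formats: delimited text (comma or tab separated, no header, rows are
observations, '.' decimal point) and NumPy's ``.npy`` binary array
container.  The writer mirrors the reader so round-trips are lossless for
binary and accurate to the printed precision (%.17g, i.e. full double) for
text.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = ["read_matrix", "write_matrix"]


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("delimited", "binary"):
            raise ValueError(f"unknown matrix format {fmt!r}")
        return fmt
    return "binary" if os.fspath(path).endswith(".npy") else "delimited"


def read_matrix(path, fmt: str | None = None) -> np.ndarray:
    """Read an n x d matrix from ``path``.

    ``fmt`` is "delimited" or "binary"; by default it is inferred from the
    ``.npy`` extension.  Distinct errors are raised for an empty file, a
    ragged row (naming the line) and a non-numeric cell (naming line and
    column).
    """
    fmt = _detect_format(path, fmt)
    if fmt == "binary":
        arr = np.load(path, allow_pickle=False)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a 1-D or 2-D array, got ndim={arr.ndim}")
        return np.asarray(arr, dtype=float)

    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = "\t" if "\t" in lines[0] else ","
    rows = []
    width = None
    for idx, ln in enumerate(lines, start=1):
        cells = ln.split(delim)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row at line {idx} ({len(cells)} fields, expected {width})"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            bad = next(c for c in cells if not _is_float(c))
            raise ValueError(
                f"{path}: non-numeric cell {bad!r} at line {idx}"
            ) from exc
    return np.asarray(rows, dtype=float)


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_matrix(A: np.ndarray, path, fmt: str | None = None, delimiter: str = ",") -> None:
    """Write ``A`` to ``path`` in the format the reader understands."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    fmt = _detect_format(path, fmt)
    if fmt == "binary":
        with open(path, "wb") as fh:  # np.save would silently append ".npy"
            np.save(fh, A)
    else:
        np.savetxt(path, A, fmt="%.17g", delimiter=delimiter)
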
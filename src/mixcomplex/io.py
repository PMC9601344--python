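"""Readers and writers for streams, responsibility matrices and results.

Two stream layouts are supported:

* ``directory`` — one numeric CSV per time step, ordered lexicographically
  by filename;
* ``long`` — a single CSV with a ``t`` column (contiguous, starting at 1)
  followed by the feature columns.

All CSVs are UTF-8 with header rows and '.' decimal separators.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_stream",
    "write_stream",
    "read_gamma",
    "read_matrix",
    "write_manifest",
]


def read_matrix(path) -> np.ndarray:
    """Read one numeric CSV (header row) as a float matrix."""
    df = pd.read_csv(path)
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix CSV ({exc})") from exc


def read_gamma(path, weight_column: bool = False):
    """Read a responsibility CSV; optionally split off a final weight column.

    Returns ``(gamma, weights)`` with ``weights`` None unless
    ``weight_column`` is set.
    """
    mat = read_matrix(path)
    if weight_column:
        if mat.shape[1] < 2:
            raise ValueError(f"{path}: need at least 2 columns to hold weights")
        return mat[:, :-1], mat[:, -1]
    return mat, None


def read_stream(path, layout: str = "auto") -> list[np.ndarray]:
    """Read a time-indexed stream of data matrices.

    ``layout`` is ``directory``, ``long``, or ``auto`` (directory if the
    path is one, long otherwise).  All steps must share the feature count;
    in long layout, ``t`` must be contiguous from 1 (rows may be shuffled).
    """
    path = Path(path)
    if layout == "auto":
        layout = "directory" if path.is_dir() else "long"
    if layout == "directory":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".csv")
        if not files:
            raise ValueError(f"{path}: no CSV files found")
        stream = []
        for t, f in enumerate(files, start=1):
            mat = read_matrix(f)
            if mat.size == 0:
                raise ValueError(f"step t={t} ({f.name}) is empty")
            stream.append(mat)
    elif layout == "long":
        df = pd.read_csv(path)
        if "t" not in df.columns:
            raise ValueError(f"{path}: long layout requires a 't' column")
        t_vals = sorted(df["t"].unique())
        expected = list(range(1, len(t_vals) + 1))
        if t_vals != expected:
            missing = sorted(set(expected) - set(t_vals))
            label = f"t={missing[0]}" if missing else f"t values {t_vals[:5]}"
            raise ValueError(
                f"{path}: time steps must be contiguous from 1; problem at {label}"
            )
        feats = [c for c in df.columns if c != "t"]
        stream = [
            df.loc[df["t"] == t, feats].to_numpy(dtype=float) for t in expected
        ]
    else:
        raise ValueError("layout must be 'directory', 'long' or 'auto'")
    d = stream[0].shape[1]
    for t, mat in enumerate(stream, start=1):
        if mat.shape[1] != d:
            raise ValueError(f"step t={t} has {mat.shape[1]} features, expected {d}")
    return stream


def write_stream(stream, out_dir) -> list[Path]:
    """Write one CSV per step (``step_001.csv``, ...) into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, mat in enumerate(stream, start=1):
        mat = np.atleast_2d(np.asarray(mat))
        cols = [f"x{j + 1}" for j in range(mat.shape[1])]
        p = out_dir / f"step_{t:03d}.csv"
        pd.DataFrame(mat, columns=cols).to_csv(p, index=False)
        paths.append(p)
    return paths


def write_manifest(path, **entries) -> None:
    """Write a reproducibility manifest (config, seeds, version) as JSON."""
    from . import __version__

    payload = {"mixcomplex_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
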
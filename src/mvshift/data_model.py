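"""Core containers and I/O for three-way (matrix-variate) data.

A *matrix sample* is a collection of N observations, each a real P×T
matrix — the natural container for longitudinal multivariate data
(P variables over T occasions per subject) and other three-way layouts.

Two on-disk layouts are supported:

``long``
    A delimited text file (comma default, tab accepted) with header
    ``obs_id,row,col,value`` and an optional trailing ``label`` column.
    Indices are 1-based in files and 0-based in memory.  The order of
    first appearance of ``obs_id`` is authoritative for label alignment.

``dir``
    A directory with one whitespace-delimited P×T matrix per file,
    lexicographic filename order = observation order, plus an optional
    ``labels.txt`` (one integer per line).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MatrixSample",
    "Partition",
    "read_sample",
    "write_sample",
    "standardize",
]


@dataclass(frozen=True)
class MatrixSample:
    """N observations of a P×T real matrix, with optional integer labels."""

    values: np.ndarray  # shape (N, P, T)
    labels: np.ndarray | None = None  # shape (N,), int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"values must be a (N, P, T) array, got ndim={values.ndim}")
        if values.shape[0] < 1:
            raise ValueError("a sample needs at least one observation")
        if not np.isfinite(values).all():
            raise ValueError("all matrix entries must be finite")
        object.__setattr__(self, "values", values)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=int)
            if labels.shape != (values.shape[0],):
                raise ValueError(
                    f"labels must have length N={values.shape[0]}, got {labels.shape}"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    @property
    def dim(self) -> int:
        """Flattened dimension d = P·T."""
        return self.n_rows * self.n_cols

    def flat(self) -> np.ndarray:
        """Observations as stacked row vectors, shape (N, P·T)."""
        return self.values.reshape(self.n_obs, -1)


@dataclass(frozen=True)
class Partition:
    """A hard clustering: labels in 1..G and the G located mode matrices."""

    labels: np.ndarray  # shape (N,), values in 1..G
    modes: np.ndarray  # shape (G, P, T)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        modes = np.asarray(self.modes, dtype=float)
        if modes.ndim != 3:
            raise ValueError("modes must be a (G, P, T) array")
        g = modes.shape[0]
        if labels.min(initial=1) < 1 or (g and labels.max(initial=g) > g):
            raise ValueError("labels must lie in 1..G")
        present = np.unique(labels)
        if len(present) != g or not np.array_equal(present, np.arange(1, g + 1)):
            raise ValueError("every mode must have at least one member")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "modes", modes)

    @property
    def n_clusters(self) -> int:
        return self.modes.shape[0]

    def equivalent(self, other: "Partition") -> bool:
        """Equality up to a bijective relabeling of cluster ids."""
        a, b = self.labels, other.labels
        if a.shape != b.shape:
            return False
        # same clustering iff the label pair mapping is one-to-one both ways
        pairs = set(zip(a.tolist(), b.tolist()))
        return len(pairs) == len(set(a.tolist())) == len(set(b.tolist()))


def _read_long(path: str, sep: str | None) -> MatrixSample:
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    expected = ["obs_id", "row", "col", "value"]
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if cols[:4] != expected:
        raise ValueError(f"long layout requires header obs_id,row,col,value; got {cols}")
    has_label = "label" in cols
    for name in ("row", "col"):
        df[name] = df[name].astype(int)
    try:
        df["value"] = df["value"].astype(float)
    except ValueError:
        bad = pd.to_numeric(df["value"], errors="coerce").isna()
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
        raise ValueError(f"non-numeric value at line {line} of {path}") from None

    obs_ids = df["obs_id"].drop_duplicates().tolist()
    p = int(df["row"].max())
    t = int(df["col"].max())
    n = len(obs_ids)
    index = {o: i for i, o in enumerate(obs_ids)}
    values = np.full((n, p, t), np.nan)
    values[df["obs_id"].map(index), df["row"] - 1, df["col"] - 1] = df["value"]
    if np.isnan(values).any():
        i, r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"ragged data: missing cell (obs={obs_ids[i]}, row={r + 1}, col={c + 1})"
        )
    labels = None
    if has_label:
        lab = df.drop_duplicates("obs_id")["label"].astype(int).to_numpy()
        labels = lab
    return MatrixSample(values, labels)


def _read_dir(path: str) -> MatrixSample:
    names = sorted(
        f for f in os.listdir(path)
        if f != "labels.txt" and not f.startswith(".")
    )
    if not names:
        raise ValueError(f"no matrix files in {path}")
    mats = [np.loadtxt(os.path.join(path, f), ndmin=2) for f in names]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"matrix files disagree on shape: {sorted(shapes)}")
    labels = None
    labfile = os.path.join(path, "labels.txt")
    if os.path.exists(labfile):
        labels = np.loadtxt(labfile, dtype=int, ndmin=1)
    return MatrixSample(np.stack(mats), labels)


def read_sample(path: str, layout: str = "long", sep: str | None = None) -> MatrixSample:
    """Read a MatrixSample from disk (``layout`` = 'long' or 'dir')."""
    if layout == "long":
        return _read_long(path, sep)
    if layout == "dir":
        return _read_dir(path)
    raise ValueError(f"unknown layout {layout!r}; expected 'long' or 'dir'")


def write_sample(sample: MatrixSample, path: str, layout: str = "long", sep: str = ",") -> None:
    """Write a MatrixSample; exact inverse of :func:`read_sample`."""
    if layout == "long":
        n, p, t = sample.values.shape
        obs, row, col = np.meshgrid(
            np.arange(1, n + 1), np.arange(1, p + 1), np.arange(1, t + 1), indexing="ij"
        )
        data = {
            "obs_id": obs.ravel(),
            "row": row.ravel(),
            "col": col.ravel(),
            "value": sample.values.ravel(),
        }
        if sample.labels is not None:
            data["label"] = np.repeat(sample.labels, p * t)
        pd.DataFrame(data).to_csv(path, sep=sep, index=False)
    elif layout == "dir":
        os.makedirs(path, exist_ok=True)
        width = len(str(sample.n_obs))
        for i, m in enumerate(sample.values, start=1):
            np.savetxt(os.path.join(path, f"obs_{i:0{width}d}.txt"), m)
        if sample.labels is not None:
            np.savetxt(os.path.join(path, "labels.txt"), sample.labels, fmt="%d")
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'long' or 'dir'")


def standardize(sample: MatrixSample, ddof: int = 0) -> MatrixSample:
    """Z-score each (p,t) cell across the N observations.

    Cells with zero spread are centered only.  ``ddof=0`` uses the
    denominator N (the package default, recorded in config output).
    """
    if sample.n_obs < 2:
        raise ValueError("cannot standardize a single observation")
    mean = sample.values.mean(axis=0)
    sd = sample.values.std(axis=0, ddof=ddof)
    scale = np.where(sd > 0, sd, 1.0)
    return MatrixSample((sample.values - mean) / scale, sample.labels)
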
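"""File formats: count panels, adjacency (edge list / GAL / dense), outputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .data import CountData
from .graph import AreaGraph, border_sharing_matrix
from .synthetic import SimulatedDataset

__all__ = [
    "read_count_data",
    "write_count_data",
    "read_adjacency",
    "read_edge_list_csv",
    "read_gal",
    "read_dense_csv",
    "write_edge_list_csv",
    "write_truth",
    "read_truth",
    "write_samples_csv",
    "write_summary_json",
]

PathLike = Union[str, Path]


def read_count_data(path: PathLike) -> CountData:
    """Load a long-format count panel from CSV.

    Required columns: ``area_id``, ``time``, ``observed``, ``expected``;
    any further numeric columns are treated as covariates.  The panel must
    be complete (every area observed at every time) with no duplicated
    (area, time) rows; areas and times are sorted and indexed internally.
    """
    df = pd.read_csv(path)
    required = ["area_id", "time", "observed", "expected"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"count CSV missing columns {missing}")
    if df.duplicated(["area_id", "time"]).any():
        raise ValueError("duplicated (area_id, time) rows")
    areas = sorted(df["area_id"].unique())
    times = sorted(df["time"].unique())
    n, T = len(areas), len(times)
    if len(df) != n * T:
        raise ValueError("incomplete panel: some (area, time) cells are missing")
    df = df.sort_values(["area_id", "time"])
    Y = df["observed"].to_numpy().reshape(n, T)
    E = df["expected"].to_numpy(dtype=float).reshape(n, T)
    covars = [c for c in df.columns if c not in required]
    X = None
    if covars:
        X = np.stack(
            [df[c].to_numpy(dtype=float).reshape(n, T) for c in covars], axis=2
        )
    return CountData(Y=Y, E=E, X=X, area_ids=areas, times=times)


def write_count_data(data: CountData, path: PathLike) -> None:
    rows = []
    for i, a in enumerate(data.area_ids):
        for t, tt in enumerate(data.times):
            row = {
                "area_id": a,
                "time": tt,
                "observed": int(data.Y[i, t]),
                "expected": float(data.E[i, t]),
            }
            if data.X is not None:
                for j in range(data.p):
                    row[f"x{j + 1}"] = float(data.X[i, t, j])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_edge_list_csv(path: PathLike) -> AreaGraph:
    """Adjacency from a two-column CSV of area-id pairs."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two id columns")
    a, b = df.columns[:2]
    ids = sorted(set(df[a]) | set(df[b]))
    return border_sharing_matrix(list(zip(df[a], df[b])), ids=ids)


def read_gal(path: PathLike) -> AreaGraph:
    """Adjacency from a GAL neighbour file.

    Header line: ``n`` (optionally preceded/followed by extra tokens, as
    written by common GIS tools); then pairs of lines: ``id n_neighbours``
    followed by the neighbour ids.
    """
    tokens_per_line = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = tokens_per_line[0]
    n = int(header[1] if len(header) > 1 else header[0])
    flat = [tok for ln in tokens_per_line[1:] for tok in ln]
    pos = 0
    neighbours = {}
    while pos < len(flat):
        area, deg = flat[pos], int(flat[pos + 1])
        pos += 2
        neighbours[area] = flat[pos : pos + deg]
        pos += deg
    if len(neighbours) != n:
        raise ValueError(f"GAL header says {n} areas, found {len(neighbours)}")
    ids = sorted(neighbours)
    edges = [(a, b) for a, nbrs in neighbours.items() for b in nbrs]
    return border_sharing_matrix(edges, ids=ids)


def read_dense_csv(path: PathLike) -> AreaGraph:
    """Adjacency from a dense 0/1 CSV matrix (no header)."""
    W = np.loadtxt(path, delimiter=",")
    return AreaGraph.from_matrix(W)


def read_adjacency(path: PathLike) -> AreaGraph:
    """Dispatch on file shape: ``.gal`` files, square dense CSV, else edge list."""
    path = Path(path)
    if path.suffix.lower() == ".gal":
        return read_gal(path)
    try:
        df = pd.read_csv(path, header=None)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"cannot parse adjacency file {path}: {exc}") from exc
    arr = df.to_numpy()
    if arr.shape[0] == arr.shape[1] and arr.shape[0] > 2:
        try:
            return AreaGraph.from_matrix(arr.astype(float))
        except (ValueError, TypeError):
            pass
    return read_edge_list_csv(path)


def write_edge_list_csv(G: AreaGraph, path: PathLike) -> None:
    rows = [
        {"area_a": G.ids[a], "area_b": G.ids[b]} for a, b in sorted(G.edges)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth(sim: SimulatedDataset, path: PathLike) -> None:
    """True risks, means and level labels of a simulated dataset (long CSV)."""
    rows = []
    data = sim.data
    for i, a in enumerate(data.area_ids):
        for t, tt in enumerate(data.times):
            rows.append(
                {
                    "area_id": a,
                    "time": tt,
                    "mu": float(sim.mu[i, t]),
                    "risk": float(sim.risk[i, t]),
                    "label": int(sim.labels[i, t]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth(path: PathLike):
    """Return (risk, labels) matrices from a truth CSV."""
    df = pd.read_csv(path).sort_values(["area_id", "time"])
    n = df["area_id"].nunique()
    T = df["time"].nunique()
    risk = df["risk"].to_numpy(dtype=float).reshape(n, T)
    labels = df["label"].to_numpy(dtype=np.int64).reshape(n, T)
    return risk, labels


def write_samples_csv(samples, path: PathLike) -> None:
    """Thinned draws as a long CSV (iteration, chain, parameter, value)."""
    recs = []
    T = samples.theta.shape[1]
    for s in range(samples.n_samples):
        ch = int(samples.chain[s])
        recs.append((s, ch, "beta0", samples.beta[s, 0]))
        recs.append((s, ch, "sigma2", samples.sigma2[s]))
        recs.append((s, ch, "alpha", samples.alpha[s]))
        recs.append((s, ch, "deviance", samples.deviance[s]))
        for t in range(T):
            recs.append((s, ch, f"theta[{t + 1}]", samples.theta[s, t]))
            recs.append((s, ch, f"tau2[{t + 1}]", samples.tau2[s, t]))
            recs.append((s, ch, f"rho[{t + 1}]", samples.rho[s, t]))
            recs.append((s, ch, f"W_c[{t + 1}]", samples.w_c[s, t]))
            recs.append((s, ch, f"W_k[{t + 1}]", samples.w_k[s, t]))
    pd.DataFrame(recs, columns=["iteration", "chain", "parameter", "value"]).to_csv(
        path, index=False
    )


def write_summary_json(summary, path: PathLike) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))
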
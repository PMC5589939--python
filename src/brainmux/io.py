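"""On-disk formats: dense CSV matrices, edge-list TSV, JSON manifests,
metrics TSV. All node indexing on disk is 0-based; matrices are written with
6-decimal fixed point so roundtrips are exact to 1e-6.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandScheme
from .spectral import BandConnectome

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_band_connectome",
    "read_band_connectome",
    "write_edge_list",
    "read_edge_list",
    "adjacency_to_edge_list",
    "edge_list_to_adjacency",
    "write_manifest",
    "read_manifest",
]


def write_matrix_csv(path: str | Path, W: np.ndarray) -> None:
    """n x n matrix as comma-separated rows, no header, 6-decimal fixed point."""
    W = np.asarray(W, dtype=float)
    np.savetxt(path, W, fmt="%.6f", delimiter=",")


def read_matrix_csv(path: str | Path, require_symmetric: bool = True) -> np.ndarray:
    """Read and validate a dense square matrix; errors carry line numbers."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                row = [float(tok) for tok in line.split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            rows.append((lineno, row))
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    n = len(rows[0][1])
    for lineno, row in rows:
        if len(row) != n:
            raise ValueError(f"{path}:{lineno}: expected {n} columns, got {len(row)}")
    W = np.array([r for _, r in rows])
    if W.shape[0] != n:
        raise ValueError(f"{path}: matrix is {W.shape[0]}x{n}, not square")
    bad = np.argwhere(~np.isfinite(W))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}:{rows[i][0]}: non-finite value at column {j}")
    if require_symmetric and not np.allclose(W, W.T, atol=1e-9):
        i, j = np.argwhere(~np.isclose(W, W.T, atol=1e-9))[0]
        raise ValueError(f"{path}: asymmetric at ({i}, {j})")
    return W


def write_band_connectome(outdir: str | Path, bc: BandConnectome, prefix: str = "") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for b, band in enumerate(bc.scheme):
        p = outdir / f"{prefix}{band.name}.csv"
        write_matrix_csv(p, bc.matrices[b])
        paths.append(p)
    return paths


def read_band_connectome(
    indir: str | Path, scheme: BandScheme = DEFAULT_BANDS, prefix: str = ""
) -> BandConnectome:
    indir = Path(indir)
    mats = []
    for band in scheme:
        p = indir / f"{prefix}{band.name}.csv"
        if not p.exists():
            raise FileNotFoundError(f"missing matrix for band {band.name!r}: {p}")
        mats.append(read_matrix_csv(p))
    return BandConnectome(matrices=np.stack(mats), scheme=scheme)


def adjacency_to_edge_list(A: np.ndarray) -> pd.DataFrame:
    """Upper-triangle edges as (i, j, weight) with i < j, 0-based."""
    A = np.asarray(A, dtype=float)
    iu, ju = np.nonzero(np.triu(A, k=1))
    return pd.DataFrame({"i": iu, "j": ju, "weight": A[iu, ju]})


def edge_list_to_adjacency(edges: pd.DataFrame, n: int) -> np.ndarray:
    A = np.zeros((n, n))
    for _, row in edges.iterrows():
        i, j = int(row["i"]), int(row["j"])
        if not (0 <= i < j < n):
            raise ValueError(f"edge ({i}, {j}) invalid for n={n} (need 0 <= i < j < n)")
        A[i, j] = A[j, i] = row["weight"]
    return A


def write_edge_list(path: str | Path, A: np.ndarray) -> None:
    adjacency_to_edge_list(A).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, n: int) -> np.ndarray:
    edges = pd.read_csv(path, sep="\t")
    missing = {"i", "j", "weight"} - set(edges.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return edge_list_to_adjacency(edges, n)


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        try:
            manifest = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: invalid JSON ({exc})") from None
    if "subjects" not in manifest:
        raise ValueError(f"{path}: manifest must contain a 'subjects' list")
    for k, subj in enumerate(manifest["subjects"]):
        for key in ("id", "group"):
            if key not in subj:
                raise ValueError(f"{path}: subject #{k} missing required key {key!r}")
        if subj["group"] not in ("AD", "HC"):
            raise ValueError(
                f"{path}: subject {subj['id']!r} has unknown group {subj['group']!r}"
            )
    return manifest
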
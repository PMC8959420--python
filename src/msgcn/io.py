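"""Readers and writers: GIFTI surfaces/labels/functional data, plain-matrix
files, sparse-triplet debug dumps, model checkpoints and run manifests.

GIFTI handling goes through nibabel.  Plain-text formats are provided for
every object so that fixtures and debugging artifacts stay human-readable:
whitespace-delimited matrices for time series and fingerprints, integer
vectors for label maps, ``i j value`` triplets for sparse operators.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.sparse as sp
import yaml

from .chebnet import ChebLayerParams, MsgcnModel
from .masked_training import ParcellationMap
from .signals import GroupAtlas, SessionTimeSeries
from .surface import SurfaceMesh

__all__ = [
    "load_surface",
    "save_surface",
    "load_labels",
    "save_labels",
    "load_timeseries",
    "save_timeseries",
    "load_vertex_data",
    "save_sparse_triplets",
    "load_sparse_triplets",
    "save_checkpoint",
    "load_checkpoint",
    "load_run_config",
    "write_manifest",
    "config_hash",
]

_NIFTI_INTENT_POINTSET = 1008
_NIFTI_INTENT_TRIANGLE = 1009
_NIFTI_INTENT_LABEL = 1002


def _ext(path: Path) -> str:
    name = path.name.lower()
    for known in (".surf.gii", ".label.gii", ".func.gii", ".gii"):
        if name.endswith(known):
            return known
    return path.suffix.lower()


def load_surface(path: str | Path, cortex_mask: np.ndarray | None = None) -> SurfaceMesh:
    """Read a triangle mesh from GIFTI (.surf.gii) or a .npz/.txt pair."""
    path = Path(path)
    ext = _ext(path)
    if ext in (".surf.gii", ".gii"):
        img = nib.load(str(path))
        coords = tris = None
        for arr in img.darrays:
            if arr.intent == _NIFTI_INTENT_POINTSET:
                coords = np.asarray(arr.data, dtype=float)
            elif arr.intent == _NIFTI_INTENT_TRIANGLE:
                tris = np.asarray(arr.data, dtype=np.int64)
        if coords is None or tris is None:
            raise ValueError(f"{path}: GIFTI surface needs POINTSET and TRIANGLE arrays")
        return SurfaceMesh(coordinates=coords, triangles=tris, cortex_mask=cortex_mask)
    if ext == ".npz":
        with np.load(path) as z:
            return SurfaceMesh(
                coordinates=z["coordinates"],
                triangles=z["triangles"],
                cortex_mask=z["cortex_mask"] if "cortex_mask" in z else cortex_mask,
            )
    raise ValueError(
        f"{path}: unsupported surface format {ext!r} (supported: .surf.gii, .npz)"
    )


def save_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    ext = _ext(path)
    if ext in (".surf.gii", ".gii"):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.coordinates.astype(np.float32),
                    intent=_NIFTI_INTENT_POINTSET,
                ),
                nib.gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32), intent=_NIFTI_INTENT_TRIANGLE
                ),
            ]
        )
        nib.save(img, str(path))
    elif ext == ".npz":
        np.savez(
            path,
            coordinates=mesh.coordinates,
            triangles=mesh.triangles,
            cortex_mask=mesh.cortex_mask,
        )
    else:
        raise ValueError(f"{path}: unsupported surface format {ext!r}")


def load_labels(path: str | Path, expected_n: int | None = None):
    """Per-vertex integer labels from GIFTI label files or text vectors.

    Returns a plain int array; wrap in GroupAtlas/ParcellationMap as needed.
    """
    path = Path(path)
    ext = _ext(path)
    if ext in (".label.gii", ".gii"):
        img = nib.load(str(path))
        labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    elif ext in (".txt", ".csv", ".tsv"):
        labels = np.loadtxt(path, dtype=np.int64)
    elif ext == ".npy":
        labels = np.load(path).astype(np.int64)
    else:
        raise ValueError(
            f"{path}: unsupported label format {ext!r} "
            "(supported: .label.gii, .txt, .csv, .tsv, .npy)"
        )
    labels = np.atleast_1d(labels)
    if expected_n is not None and labels.shape[0] != expected_n:
        raise ValueError(
            f"{path}: {labels.shape[0]} labels but expected {expected_n}"
        )
    return labels


def save_labels(labels: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    ext = _ext(path)
    labels = np.asarray(labels, dtype=np.int64)
    if ext in (".label.gii", ".gii"):
        darray = nib.gifti.GiftiDataArray(
            labels.astype(np.int32), intent=_NIFTI_INTENT_LABEL
        )
        table = nib.gifti.GiftiLabelTable()
        for k in np.unique(labels):
            lbl = nib.gifti.GiftiLabel(key=int(k))
            lbl.label = f"parcel_{int(k)}"
            table.labels.append(lbl)
        img = nib.gifti.GiftiImage(darrays=[darray])
        img.labeltable = table
        nib.save(img, str(path))
    elif ext in (".txt", ".csv", ".tsv"):
        np.savetxt(path, labels, fmt="%d")
    elif ext == ".npy":
        np.save(path, labels)
    else:
        raise ValueError(f"{path}: unsupported label format {ext!r}")


def load_timeseries(
    path: str | Path, tr: float, expected_n: int | None = None, **ids
) -> SessionTimeSeries:
    """Time series from GIFTI functional files (one map per timepoint) or a
    dense matrix file (rows = vertices)."""
    path = Path(path)
    ext = _ext(path)
    if ext in (".func.gii", ".gii"):
        img = nib.load(str(path))
        data = np.column_stack([np.asarray(d.data, dtype=float) for d in img.darrays])
    elif ext in (".txt", ".csv", ".tsv"):
        data = np.loadtxt(path, delimiter="," if ext == ".csv" else None)
    elif ext == ".npy":
        data = np.load(path)
    else:
        raise ValueError(
            f"{path}: unsupported time-series format {ext!r} "
            "(supported: .func.gii, .txt, .csv, .tsv, .npy)"
        )
    if expected_n is not None and data.shape[0] != expected_n:
        raise ValueError(
            f"{path}: {data.shape[0]} vertex rows but expected {expected_n}"
        )
    return SessionTimeSeries(data=data, tr=tr, **ids)


def save_timeseries(ts: SessionTimeSeries, path: str | Path) -> None:
    path = Path(path)
    ext = _ext(path)
    if ext in (".func.gii", ".gii"):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(col.astype(np.float32))
                for col in ts.data.T
            ]
        )
        nib.save(img, str(path))
    elif ext in (".txt", ".tsv"):
        np.savetxt(path, ts.data)
    elif ext == ".npy":
        np.save(path, ts.data)
    else:
        raise ValueError(f"{path}: unsupported time-series format {ext!r}")


def load_vertex_data(path: str | Path, expected_n: int | None = None):
    """Extension-dispatched loader for any per-vertex vector or matrix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = _ext(path)
    if ext == ".label.gii":
        return load_labels(path, expected_n=expected_n)
    if ext == ".func.gii":
        img = nib.load(str(path))
        data = np.column_stack([np.asarray(d.data, dtype=float) for d in img.darrays])
    elif ext == ".surf.gii":
        raise ValueError(f"{path}: surface files go through load_surface")
    elif ext in (".txt", ".csv", ".tsv"):
        data = np.loadtxt(path, delimiter="," if ext == ".csv" else None)
    elif ext == ".npy":
        data = np.load(path)
    else:
        raise ValueError(
            f"{path}: unknown extension {ext!r} (supported: .label.gii, "
            ".func.gii, .txt, .csv, .tsv, .npy)"
        )
    if expected_n is not None and data.shape[0] != expected_n:
        raise ValueError(f"{path}: {data.shape[0]} rows but expected {expected_n}")
    return data


def save_sparse_triplets(matrix: sp.spmatrix, path: str | Path) -> None:
    """Debug dump: one ``i j value`` line per stored entry."""
    coo = matrix.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# shape {coo.shape[0]} {coo.shape[1]}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {float(v)!r}\n")


def load_sparse_triplets(path: str | Path) -> sp.csr_matrix:
    with open(path) as fh:
        header = fh.readline().split()
        shape = (int(header[2]), int(header[3]))
        rows, cols, vals = [], [], []
        for line in fh:
            i, j, v = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
    return sp.coo_matrix((vals, (rows, cols)), shape=shape).tocsr()


def save_checkpoint(
    model: MsgcnModel, path: str | Path, meta: dict | None = None
) -> None:
    """Self-describing archive: layer shapes/orders plus arbitrary metadata."""
    arrays: dict[str, np.ndarray] = {}
    desc = {
        "dropout_rate": model.dropout_rate,
        "activation": model.activation,
        "orders": [l.order for l in model.layers],
        "has_bias": [l.bias is not None for l in model.layers],
        "meta": meta or {},
    }
    for i, layer in enumerate(model.layers):
        arrays[f"theta_{i}"] = layer.theta
        if layer.bias is not None:
            arrays[f"bias_{i}"] = layer.bias
    arrays["__desc__"] = np.frombuffer(
        json.dumps(desc).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[MsgcnModel, dict]:
    with np.load(path) as z:
        desc = json.loads(bytes(z["__desc__"]).decode())
        layers = []
        for i, order in enumerate(desc["orders"]):
            layers.append(
                ChebLayerParams(
                    order=order,
                    theta=z[f"theta_{i}"],
                    bias=z[f"bias_{i}"] if desc["has_bias"][i] else None,
                )
            )
    model = MsgcnModel(
        layers=layers,
        dropout_rate=desc["dropout_rate"],
        activation=desc["activation"],
    )
    return model, desc["meta"]


def load_run_config(path: str | Path) -> dict:
    """YAML run configuration with schema defaults merged in."""
    defaults = {
        "seed": 0,
        "model": {"hidden": 64, "order": 3, "dropout": 0.5},
        "training": {
            "epochs": 100,
            "patience": 10,
            "weight_decay": 0.0005,
            "learning_rate": 0.001,
        },
    }
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    out = dict(defaults)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = {**out[key], **val}
        else:
            out[key] = val
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int) -> None:
    """Sidecar manifest recording what produced an artifact."""
    from . import __version__

    manifest = {
        "tool": "msgcn",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
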
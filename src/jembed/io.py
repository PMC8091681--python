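"""File I/O: count matrices (CSV/TSV dense, Matrix Market with sidecars),
label vectors, embeddings, and the reproducibility manifest.

MTX files follow the 10x convention: features as rows, cells as columns,
with ``barcodes.tsv`` / ``features.tsv`` sidecars next to the matrix file;
matrices are transposed to cells x features on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from . import __version__
from .datatypes import CountMatrix, JointConfig, JointResult, UmapKernelParams


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".tsv":
        return "tsv"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format of {path} (expected .csv/.tsv/.mtx)")


def read_modality(path: str | Path, fmt: str | None = None, name: str | None = None) -> CountMatrix:
    """Load one modality's counts.

    CSV/TSV: cells as rows, header row of feature ids, first column cell
    ids.  MTX: features x cells with barcodes/features sidecars (transposed
    on load).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    name = name or path.stem
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        values = df.to_numpy()
        if values.dtype == object:
            raise ValueError(f"{path}: non-numeric entries")
        neg = np.argwhere(values < 0)
        if neg.size:
            r, c = neg[0]
            raise ValueError(
                f"{path}: negative count at cell {df.index[r]!r}, "
                f"feature {df.columns[c]!r}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"{path}: duplicate cell ids {dups}")
        return CountMatrix(
            values=values,
            cell_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            modality_name=name,
        )
    if fmt == "mtx":
        mat = sio.mmread(path)
        mat = sp.csr_matrix(mat).T  # cells x features
        barcodes_path = path.parent / "barcodes.tsv"
        features_path = path.parent / "features.tsv"
        for p in (barcodes_path, features_path):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX sidecar {p}")
        barcodes = [l.split("\t")[0] for l in barcodes_path.read_text().splitlines() if l]
        features = [l.split("\t")[0] for l in features_path.read_text().splitlines() if l]
        if len(barcodes) != mat.shape[0]:
            raise ValueError(
                f"{path}: {len(barcodes)} barcodes but {mat.shape[0]} matrix columns"
            )
        if len(features) != mat.shape[1]:
            raise ValueError(
                f"{path}: {len(features)} features but {mat.shape[1]} matrix rows"
            )
        dense = np.asarray(mat.todense())
        if np.any(dense < 0):
            raise ValueError(f"{path}: negative counts")
        return CountMatrix(
            values=dense, cell_ids=barcodes, feature_ids=features, modality_name=name
        )
    raise ValueError(f"unknown format {fmt!r}")


def read_any_modality(path: str | Path, fmt: str | None = None, name: str | None = None):
    """Load a modality as counts, or as an already-processed real-valued
    view when entries are negative or non-integer (e.g. PCA scores)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    name = name or path.stem
    if fmt == "mtx":
        return read_modality(path, fmt, name)
    df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
    values = df.to_numpy()
    if values.dtype == object:
        raise ValueError(f"{path}: non-numeric entries")
    is_counts = np.all(values >= 0) and np.allclose(values, np.round(values))
    if is_counts:
        return read_modality(path, fmt, name)
    from .datatypes import ModalityView

    return ModalityView(
        values=values.astype(np.float64),
        modality_name=name,
        cell_ids=[str(i) for i in df.index],
        transform_log=["loaded as processed view"],
    )


def write_modality(X: CountMatrix, path: str | Path, fmt: str | None = None) -> Path:
    """Write counts as CSV/TSV (cells x features) or MTX with sidecars."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt in ("csv", "tsv"):
        df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.feature_ids)
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
    elif fmt == "mtx":
        sio.mmwrite(str(path), sp.coo_matrix(X.values.T))
        (path.parent / "barcodes.tsv").write_text("\n".join(X.cell_ids) + "\n")
        (path.parent / "features.tsv").write_text("\n".join(X.feature_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def align_modalities(modalities: list[CountMatrix]) -> list[CountMatrix]:
    """Reorder every modality to the first modality's cell order by id."""
    if not modalities:
        raise ValueError("no modalities given")
    ref = modalities[0].cell_ids
    out = [modalities[0]]
    for X in modalities[1:]:
        if X.cell_ids == ref:
            out.append(X)
            continue
        if set(X.cell_ids) != set(ref):
            raise ValueError(
                f"modality {X.modality_name!r} cell ids do not match the first modality"
            )
        pos = {c: i for i, c in enumerate(X.cell_ids)}
        order = [pos[c] for c in ref]
        out.append(
            CountMatrix(
                values=X.values[order],
                cell_ids=list(ref),
                feature_ids=list(X.feature_ids),
                modality_name=X.modality_name,
            )
        )
    return out


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a label CSV (cell_id,label; header optional single column ok)."""
    df = pd.read_csv(path)
    if df.shape[1] == 1:
        return [str(i) for i in range(len(df))], df.iloc[:, 0].to_numpy()
    return [str(c) for c in df.iloc[:, 0]], df.iloc[:, 1].to_numpy()


def write_labels(cell_ids, labels, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": list(cell_ids), "label": list(labels)}).to_csv(
        path, index=False
    )
    return path


def write_embedding(result: JointResult, path: str | Path) -> Path:
    """Embedding CSV with columns cell_id,dim1,dim2[,...]."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n, d = result.embedding.shape
    ids = result.cell_ids or [f"cell{i}" for i in range(n)]
    cols = {f"dim{i + 1}": result.embedding[:, i] for i in range(d)}
    pd.DataFrame({"cell_id": ids, **cols}).to_csv(path, index=False, float_format="%.10g")
    return path


def read_embedding(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return [str(c) for c in df["cell_id"]], df.drop(columns="cell_id").to_numpy(float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    method: str,
    config: JointConfig,
    result: JointResult,
    input_paths: list[str | Path] | None = None,
    kernel: UmapKernelParams | None = None,
) -> Path:
    """Write a run manifest sufficient to reproduce the run bit-identically:
    config snapshot, method, input checksums, seed, version, and the full
    alpha/loss trace."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "method": method,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "kernel": dataclasses.asdict(kernel) if kernel else None,
        "inputs": [
            {"path": str(Path(p).resolve()), "sha256": _sha256(Path(p))}
            for p in (input_paths or [])
        ],
        "modalities": result.modality_names,
        "final_alpha": [float(a) for a in result.weights],
        "history": [rec.to_dict() for rec in result.history],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_from_manifest(manifest: dict) -> tuple[JointConfig, UmapKernelParams | None]:
    config = JointConfig(**manifest["config"])
    kernel = UmapKernelParams(**manifest["kernel"]) if manifest.get("kernel") else None
    return config, kernel


__all__ = [
    "read_modality",
    "read_any_modality",
    "write_modality",
    "align_modalities",
    "read_labels",
    "write_labels",
    "write_embedding",
    "read_embedding",
    "write_manifest",
    "load_manifest",
    "config_from_manifest",
]
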
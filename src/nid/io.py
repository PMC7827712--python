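"""Readers, writers and report generation.

Sample matrices travel as headerless integer CSV/TSV with an optional JSON
sidecar (``<name>.json``) recording supports, seed and the train/validation
split; an HDF5 container is available for large matrices.  Binary spike
matrices (e.g. binned multi-electrode recordings) load unchanged as 0/1
columns.  Every report artifact embeds the unit, the seed and a hash of the
generating configuration so outputs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import SampleMatrix
from .joint import JointTable

__all__ = [
    "load_samples",
    "save_samples",
    "save_joint",
    "load_joint",
    "profile_frame",
    "write_report",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ----------------------------------------------------------------------
# sample matrices


def save_samples(samples: SampleMatrix, path: str | Path, fmt: str = "csv") -> Path:
    """Write a sample matrix as headerless CSV (+ JSON sidecar) or HDF5."""
    path = Path(path)
    sidecar = {
        "supports": list(samples.supports),
        "seed": samples.seed,
        "train_idx": samples.train_idx.tolist(),
        "val_idx": samples.val_idx.tolist(),
    }
    if fmt == "csv":
        np.savetxt(path, samples.data, fmt="%d", delimiter=",")
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=samples.data)
            f.attrs["sidecar"] = json.dumps(sidecar)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def load_samples(path: str | Path) -> SampleMatrix:
    """Load a sample matrix; supports are inferred as max+1 if no sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"], dtype=np.int64)
            sidecar = json.loads(f.attrs["sidecar"]) if "sidecar" in f.attrs else None
    else:
        delimiter = "\t" if path.suffix in (".tsv", ".tab") else ","
        try:
            data = np.loadtxt(path, dtype=np.int64, delimiter=delimiter, ndmin=2)
        except ValueError as err:
            raise ValueError(f"could not parse {path} as an integer matrix: {err}")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        sidecar = (
            json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None
        )
    if np.any(data < 0):
        raise ValueError("sample matrix contains negative entries")
    if sidecar is None:
        supports = tuple(max(int(v) + 1, 2) for v in data.max(axis=0))
        return SampleMatrix(data=data, supports=supports, seed=None)
    return SampleMatrix(
        data=data,
        supports=tuple(sidecar["supports"]),
        seed=sidecar.get("seed"),
        train_idx=np.array(sidecar["train_idx"], dtype=np.int64),
        val_idx=np.array(sidecar["val_idx"], dtype=np.int64),
    )


# ----------------------------------------------------------------------
# joint tables


def save_joint(joint: JointTable, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(joint.to_json())
    return path


def load_joint(path: str | Path) -> JointTable:
    return JointTable.from_json(Path(path).read_text())


# ----------------------------------------------------------------------
# reports


def profile_frame(profile) -> pd.DataFrame:
    """Tabular form of an undirected or directed profile (one row per order)."""
    return pd.DataFrame(profile.rows())


def write_report(
    out_dir: str | Path,
    name: str,
    config: dict,
    profiles: dict | None = None,
    layerwise: dict | None = None,
    per_variable: dict | None = None,
) -> Path:
    """Write a deterministic JSON + CSV report bundle.

    ``profiles`` maps labels to profile objects, ``layerwise`` maps labels to
    :class:`~nid.model.LayerwiseNLL`, ``per_variable`` maps method names to
    per-variable NLL vectors (kept in input variable order).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"name": name, "config": config, "config_hash": config_hash(config)}
    payload = dict(meta)
    frames = []
    for label, prof in (profiles or {}).items():
        df = profile_frame(prof)
        df.insert(0, "profile", label)
        frames.append(df)
        payload.setdefault("profiles", {})[label] = prof.rows()
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / f"{name}_profiles.csv", index=False
        )
    for label, lw in (layerwise or {}).items():
        df = pd.DataFrame(
            lw.matrix,
            columns=[f"x{i + 1}" for i in range(lw.matrix.shape[1])],
        )
        df.insert(0, "layer", np.arange(len(df)))
        df["sum"] = lw.sums
        df.to_csv(out_dir / f"{name}_{label}_layerwise.csv", index=False)
        payload.setdefault("layerwise", {})[label] = {
            "unit": lw.unit,
            "sums": lw.sums.tolist(),
            "deltas": lw.deltas.tolist(),
        }
    if per_variable:
        df = pd.DataFrame(per_variable)
        df.insert(0, "variable", [f"x{i + 1}" for i in range(len(df))])
        df.to_csv(out_dir / f"{name}_per_variable.csv", index=False)
        payload["per_variable"] = {k: list(map(float, v)) for k, v in per_variable.items()}
    out = out_dir / f"{name}.json"
    out.write_text(json.dumps(payload, indent=2, default=float))
    return out
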
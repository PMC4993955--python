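"""File I/O: point clouds (PLY/CSV), meshes, cohort tables.

Correspondence across samples is carried by row order, so point files are
always written and read in a fixed ordering.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ShapeSample

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_mesh",
    "read_labels",
    "write_cohort",
    "read_cohort",
    "write_truth",
]


def read_point_cloud(path) -> np.ndarray:
    """Load an (N, 3) point set from a ``.ply`` or ``.csv``/``.xyz`` file."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        obj = trimesh.load(path, process=False)
        return np.asarray(obj.vertices, dtype=float)
    return np.loadtxt(path, delimiter=",", dtype=float).reshape(-1, 3)


def write_point_cloud(path, points: np.ndarray) -> None:
    path = Path(path)
    pts = np.asarray(points, dtype=float)
    if path.suffix.lower() == ".ply":
        import trimesh

        trimesh.PointCloud(pts).export(path)
    else:
        np.savetxt(path, pts, delimiter=",", fmt="%.8f")


def read_mesh(path):
    """Load a triangulated mesh (any trimesh-supported format)."""
    import trimesh

    mesh = trimesh.load(Path(path), process=False, force="mesh")
    return mesh


def read_labels(path) -> pd.DataFrame:
    """KL label table: columns ``knee_id, kl_grade`` (kl may be blank)."""
    df = pd.read_csv(path)
    if not {"knee_id", "kl_grade"} <= set(df.columns):
        raise ValueError("labels file needs columns knee_id, kl_grade")
    return df


def load_training_samples(train_dir, labels: pd.DataFrame, bone: str) -> list[ShapeSample]:
    """Read one point file per labelled knee from ``train_dir``.

    Files are looked up as ``<knee_id>.csv`` or ``<knee_id>.ply``.
    """
    train_dir = Path(train_dir)
    samples = []
    for _, row in labels.iterrows():
        base = train_dir / str(row["knee_id"])
        for suffix in (".csv", ".ply", ".xyz"):
            p = base.with_suffix(suffix)
            if p.exists():
                kl = None if pd.isna(row["kl_grade"]) else int(row["kl_grade"])
                samples.append(
                    ShapeSample(
                        bone=bone,
                        points=read_point_cloud(p),
                        knee_id=str(row["knee_id"]),
                        kl_grade=kl,
                    )
                )
                break
        else:
            raise FileNotFoundError(f"no point file for knee {row['knee_id']} in {train_dir}")
    return samples


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("tkr", "insurance", "has_shape"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_truth(path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, cls=_NumpyEncoder))


def dump_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))
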
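"""Point-to-surface distances for segmentation accuracy checks.

The mean point-to-surface error is the standard agreement metric between a
point sampling of a bone surface (e.g. an automated segmentation) and a
reference triangulated mesh (e.g. a manual segmentation).
"""

from __future__ import annotations

import numpy as np

__all__ = ["point_triangle_distances", "min_surface_distances", "point_to_surface_error"]


def _segment_distances(p, a, b):
    """Distance from points p (P,1,3) to segments a->b (T,3); returns (P,T)."""
    ab = b - a  # (T,3)
    denom = np.einsum("ij,ij->i", ab, ab)  # (T,)
    denom = np.where(denom > 0.0, denom, 1.0)
    ap = p - a  # (P,T,3)
    t = np.einsum("ptj,tj->pt", ap, ab) / denom
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


def point_triangle_distances(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Euclidean distances from each point to each triangle.

    Parameters
    ----------
    points : (P, 3) ndarray
    triangles : (T, 3, 3) ndarray
        Vertex coordinates per triangle.

    Returns
    -------
    (P, T) ndarray of distances.

    Notes
    -----
    The distance to a triangle is the plane distance when the orthogonal
    projection falls inside the triangle (by barycentric test) and otherwise
    the minimum distance to its three edges; degenerate (zero-area) triangles
    fall back to edge distances alone.
    """
    pts = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (P, 3)")
    if tri.ndim != 3 or tri.shape[1:] != (3, 3):
        raise ValueError("triangles must be (T, 3, 3)")

    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e0, e1 = b - a, c - a
    n = np.cross(e0, e1)  # (T,3)
    n_len = np.linalg.norm(n, axis=1)
    ok = n_len > 0.0
    n_hat = np.where(ok[:, None], n / np.where(ok, n_len, 1.0)[:, None], 0.0)

    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    den = d00 * d11 - d01 * d01
    den_safe = np.where(np.abs(den) > 0.0, den, 1.0)

    p = pts[:, None, :]  # (P,1,3)
    ap = p - a  # (P,T,3)
    plane = np.einsum("ptj,tj->pt", ap, n_hat)  # signed plane distance
    proj = ap - plane[..., None] * n_hat  # projection in triangle plane
    d20 = np.einsum("ptj,tj->pt", proj, e0)
    d21 = np.einsum("ptj,tj->pt", proj, e1)
    v = (d11 * d20 - d01 * d21) / den_safe
    w = (d00 * d21 - d01 * d20) / den_safe
    eps = 1e-12
    inside = (v >= -eps) & (w >= -eps) & (v + w <= 1.0 + eps) & ok & (np.abs(den) > 0.0)

    d_edges = np.minimum(
        _segment_distances(p, a, b),
        np.minimum(_segment_distances(p, b, c), _segment_distances(p, c, a)),
    )
    return np.where(inside, np.abs(plane), d_edges)


def _as_vertices_faces(mesh, faces):
    if faces is not None:
        return np.asarray(mesh, dtype=float), np.asarray(faces, dtype=int)
    # duck-typed trimesh.Trimesh
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=int)


def min_surface_distances(points, mesh, faces=None, chunk: int = 512) -> np.ndarray:
    """Minimum distance from each point to a triangulated surface."""
    vertices, f = _as_vertices_faces(mesh, faces)
    if len(f) == 0:
        raise ValueError("mesh has no faces")
    tri = vertices[f]
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("no points supplied")
    out = np.empty(len(pts))
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        out[start : start + chunk] = point_triangle_distances(block, tri).min(axis=1)
    return out


def point_to_surface_error(points, mesh, faces=None) -> float:
    """Mean point-to-surface distance (mm) from ``points`` to ``mesh``.

    ``mesh`` may be a ``trimesh.Trimesh`` or a vertex array combined with a
    ``faces`` index array.
    """
    return float(min_surface_distances(points, mesh, faces).mean())
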
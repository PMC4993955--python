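"""Rigid alignment: Kabsch superimposition and generalized Procrustes analysis.

Alignment is translation + rotation only.  Scaling is deliberately never
removed: osteoarthritic bone change includes expansion of the bone surface,
which is part of the signal the OA shape vector must capture.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DegenerateShapeError

__all__ = ["kabsch", "rigid_align", "gpa_align"]


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Returns ``(R, t)`` with ``R`` a proper rotation (det = +1) such that
    ``source @ R.T + t`` minimises the summed squared distance to ``target``.
    No scaling component is estimated.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must both be (N, 3) with equal N")
    src_c = src.mean(axis=0)
    tgt_c = tgt.mean(axis=0)
    h = (src - src_c).T @ (tgt - tgt_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tgt_c - r @ src_c
    return r, t


def rigid_align(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``points`` rigidly superimposed onto ``target``."""
    r, t = kabsch(points, target)
    return np.asarray(points, dtype=float) @ r.T + t


def _check_stack(point_sets) -> np.ndarray:
    arrs = [np.asarray(p, dtype=float) for p in point_sets]
    if len(arrs) < 2:
        raise ValueError("need at least two point sets")
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError(
                f"all point sets must share one shape; got {a.shape} vs {shape}"
            )
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("point sets must be (N, 3)")
        if not np.all(np.isfinite(a)):
            raise ValueError("point set contains non-finite coordinates")
        if np.allclose(a.std(axis=0), 0.0):
            raise DegenerateShapeError("all points coincide; cannot align")
    return np.stack(arrs)


def gpa_align(
    point_sets,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized Procrustes alignment without scaling.

    Each point set is centred, then iteratively rotated onto the current
    consensus (the coordinate-wise mean shape, itself re-centred at the
    origin) until the mean per-point displacement of the samples during a
    pass falls below ``tol`` - so already-aligned input is a fixed point and
    re-alignment is the identity.

    Parameters
    ----------
    point_sets : sequence of (N, 3) arrays
        Corresponded point sets of one bone.
    tol : float
        Convergence threshold on the mean displacement (mm) of the consensus.
    max_iter : int
        Iteration cap.

    Returns
    -------
    aligned : (n, N, 3) ndarray
    mean_shape : (N, 3) ndarray
        The converged consensus, centred at the origin.
    """
    arrs = _check_stack(point_sets)
    arrs = arrs - arrs.mean(axis=1, keepdims=True)
    # initialize from the coordinate-wise mean so that already-aligned input
    # is a fixed point (re-alignment is then the identity); fall back to the
    # first sample when orientations cancel
    mean = arrs.mean(axis=0)
    if np.allclose(mean.std(axis=0), 0.0):
        mean = arrs[0].copy()
    for _ in range(max_iter):
        moved = 0.0
        for i in range(arrs.shape[0]):
            r, t = kabsch(arrs[i], mean)
            new = arrs[i] @ r.T + t
            moved += float(np.mean(np.linalg.norm(new - arrs[i], axis=1)))
            arrs[i] = new
        new_mean = arrs.mean(axis=0)
        mean = new_mean - new_mean.mean(axis=0)
        if moved / arrs.shape[0] < tol:
            break
    return arrs, mean
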
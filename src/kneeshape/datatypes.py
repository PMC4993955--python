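"""Core domain containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Bones modelled per knee, in canonical order.
BONES = ("femur", "tibia", "patella")


class DegenerateShapeError(ValueError):
    """Raised when a point set or shape model is geometrically degenerate."""


@dataclass
class ShapeSample:
    """One bone's corresponded 3D point set.

    Points carry point-to-point correspondence: row *i* refers to the same
    anatomical location in every sample of the same bone, so the point count
    must match across samples and the row ordering is meaningful.

    Parameters
    ----------
    bone : str
        One of ``femur``, ``tibia``, ``patella``.
    points : (N, 3) ndarray
        Surface point coordinates in millimetres, N >= 4.
    knee_id : str
        Identifier of the knee the sample was taken from.
    kl_grade : int or None
        Kellgren-Lawrence radiographic grade 0-4, or None when unknown.
    """

    bone: str
    points: np.ndarray
    knee_id: str = ""
    kl_grade: int | None = None

    def __post_init__(self) -> None:
        if self.bone not in BONES:
            raise ValueError(f"unknown bone {self.bone!r}; expected one of {BONES}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        if pts.shape[0] < 4:
            raise ValueError("a shape sample needs at least 4 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        if self.kl_grade is not None and self.kl_grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"kl_grade must be 0-4 or None, got {self.kl_grade}")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class VectorScore:
    """Position of one bone shape on the normalized OA vector.

    ``b`` is dimensionless: the mean non-OA training shape maps to -1 and the
    mean OA training shape to +1, with more positive values indicating more
    advanced structural osteoarthritis.
    """

    knee_id: str
    bone: str
    b: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.b):
            raise ValueError("score is not finite")
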
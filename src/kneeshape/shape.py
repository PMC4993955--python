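"""The OA shape vector model.

A statistical shape model is built from a Kellgren-Lawrence-labelled training
set of corresponded bone point sets: samples are rigidly aligned (generalized
Procrustes, no scaling), a principal-component basis of the aligned
coordinates is extracted, and the line through the mean non-OA (KL 0-1) and
mean OA (KL 2-4) training shapes in component-score space defines the OA
vector.  New shapes are projected orthogonally onto that line and the signed
position is rescaled so the non-OA group mean sits at -1 and the OA group
mean at +1.

Usage follows the Model / Results convention::

    model = ShapeVectorModel(training_samples)
    res = model.fit(var_frac=0.98)
    b = res.score(sample)            # scalar OA vector value
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .align import gpa_align, rigid_align
from .datatypes import BONES, DegenerateShapeError, ShapeSample, VectorScore

__all__ = ["ShapeVectorModel", "ShapeVectorResults"]

_NON_OA_GRADES = (0, 1)
_OA_GRADES = (2, 3, 4)


class ShapeVectorModel:
    """Shape-space model builder for one bone.

    Parameters
    ----------
    samples : sequence of ShapeSample
        Training samples of a single bone with identical point counts.
        Samples with a missing KL grade are excluded from fitting (the
        group split requires labels); at least one OA (KL 2-4) and one
        non-OA (KL 0-1) sample must remain.
    """

    def __init__(self, samples):
        samples = list(samples)
        if not samples:
            raise ValueError("no training samples")
        bone = samples[0].bone
        n_points = samples[0].n_points
        for s in samples:
            if s.bone != bone:
                raise ValueError(f"mixed bones in training set: {s.bone} vs {bone}")
            if s.n_points != n_points:
                raise ValueError("training samples disagree on point count")
        self.bone = bone
        self.n_points = n_points
        self.samples = [s for s in samples if s.kl_grade is not None]
        self.n_excluded_missing_kl = len(samples) - len(self.samples)
        oa = [s.kl_grade in _OA_GRADES for s in self.samples]
        if not any(oa) or all(oa):
            raise ValueError(
                "training set must contain both OA (KL 2-4) and non-OA (KL 0-1) shapes"
            )
        self._oa_mask = np.asarray(oa)

    def fit(
        self,
        var_frac: float = 0.98,
        gpa_tol: float = 1e-7,
        gpa_max_iter: int = 100,
    ) -> "ShapeVectorResults":
        """Align, extract principal components and define the OA vector.

        ``var_frac`` selects the smallest number of components whose
        cumulative explained variance reaches that fraction.
        """
        if not (0.0 < var_frac <= 1.0):
            raise ValueError("var_frac must be in (0, 1]")
        aligned, mean_shape = gpa_align(
            [s.points for s in self.samples], tol=gpa_tol, max_iter=gpa_max_iter
        )
        n = aligned.shape[0]
        x = aligned.reshape(n, -1)
        mean_flat = x.mean(axis=0)
        xc = x - mean_flat
        # full_matrices=False: at most n-1 informative components
        _, sing, vt = np.linalg.svd(xc, full_matrices=False)
        eigvals = sing**2 / (n - 1)
        total = eigvals.sum()
        if total <= 0.0:
            raise DegenerateShapeError("training set has no shape variation")
        cum = np.cumsum(eigvals) / total
        m = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
        m = min(m, len(eigvals))
        basis = vt[:m]
        eigvals = eigvals[:m]
        scores = xc @ basis.T
        m_oa = scores[self._oa_mask].mean(axis=0)
        m_non_oa = scores[~self._oa_mask].mean(axis=0)
        if np.linalg.norm(m_oa - m_non_oa) < 1e-10:
            raise DegenerateShapeError(
                "OA and non-OA group means coincide; OA vector undefined"
            )
        return ShapeVectorResults(
            bone=self.bone,
            n_points=self.n_points,
            mean_shape=mean_flat.reshape(-1, 3),
            components=basis,
            eigenvalues=eigvals,
            m_oa=m_oa,
            m_non_oa=m_non_oa,
            n_train_oa=int(self._oa_mask.sum()),
            n_train_non_oa=int((~self._oa_mask).sum()),
            var_frac=var_frac,
            explained_var_ratio=float(cum[m - 1]),
        )


@dataclass
class ShapeVectorResults:
    """Fitted shape space plus the OA vector endpoints.

    Attributes
    ----------
    mean_shape : (N, 3) ndarray
        Procrustes consensus of the training set (model frame), mm.
    components : (M, 3N) ndarray
        Orthonormal principal-component basis rows.
    eigenvalues : (M,) ndarray
        Per-component variances (mm^2), non-increasing.
    m_oa, m_non_oa : (M,) ndarray
        Component scores of the OA / non-OA training group mean shapes.
    """

    bone: str
    n_points: int
    mean_shape: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    m_oa: np.ndarray
    m_non_oa: np.ndarray
    n_train_oa: int
    n_train_non_oa: int
    var_frac: float = 0.98
    explained_var_ratio: float = field(default=float("nan"))

    # -- geometry ---------------------------------------------------------

    def align_to_model(self, points: np.ndarray) -> np.ndarray:
        """Rigidly superimpose a raw point set onto the model mean shape."""
        pts = np.asarray(points, dtype=float)
        self._check_points(pts)
        return rigid_align(pts, self.mean_shape)

    def _check_points(self, pts: np.ndarray) -> None:
        if pts.shape != (self.n_points, 3):
            raise ValueError(
                f"expected ({self.n_points}, 3) points for {self.bone}, got {pts.shape}"
            )

    def transform(self, sample, align: bool = True) -> np.ndarray:
        """Principal-component scores of one sample (after optional alignment)."""
        pts = sample.points if isinstance(sample, ShapeSample) else np.asarray(sample, float)
        if isinstance(sample, ShapeSample) and sample.bone != self.bone:
            raise ValueError(f"sample bone {sample.bone} does not match model {self.bone}")
        self._check_points(pts)
        if align:
            pts = rigid_align(pts, self.mean_shape)
        return self.components @ (pts.reshape(-1) - self.mean_shape.reshape(-1))

    # -- scoring ----------------------------------------------------------

    def score_from_scores(self, p: np.ndarray) -> float:
        """OA vector value from component scores ``p``.

        The sample is projected orthogonally onto the line through the two
        group means; the position is affinely rescaled so the non-OA mean
        maps to -1 and the OA mean to +1.  Components of ``p`` perpendicular
        to the line do not affect the value.
        """
        p = np.asarray(p, dtype=float)
        delta = self.m_oa - self.m_non_oa
        raw = (p - self.m_non_oa) @ delta / (delta @ delta)
        return float(2.0 * raw - 1.0)

    def score(self, sample, align: bool = True) -> float:
        """OA vector value of one sample (point set or ShapeSample)."""
        return self.score_from_scores(self.transform(sample, align=align))

    def score_sample(self, sample: ShapeSample, align: bool = True) -> VectorScore:
        return VectorScore(
            knee_id=sample.knee_id, bone=self.bone, b=self.score(sample, align=align)
        )

    def score_stack(self, stack: np.ndarray, align: bool = True) -> np.ndarray:
        """Vectorized scoring of an (n, N, 3) stack of point sets."""
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3 or stack.shape[1:] != (self.n_points, 3):
            raise ValueError(f"expected (n, {self.n_points}, 3) stack")
        if align:
            stack = np.stack([rigid_align(p, self.mean_shape) for p in stack])
        xc = stack.reshape(stack.shape[0], -1) - self.mean_shape.reshape(-1)
        p = xc @ self.components.T
        delta = self.m_oa - self.m_non_oa
        raw = (p - self.m_non_oa) @ delta / (delta @ delta)
        return 2.0 * raw - 1.0

    def reconstruct(self, p: np.ndarray) -> np.ndarray:
        """Point set reconstructed from component scores (model frame)."""
        flat = self.mean_shape.reshape(-1) + np.asarray(p, float) @ self.components
        return flat.reshape(-1, 3)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize to a single ``.npz`` archive (arrays + JSON header)."""
        meta = {
            "bone": self.bone,
            "n_points": self.n_points,
            "n_train_oa": self.n_train_oa,
            "n_train_non_oa": self.n_train_non_oa,
            "var_frac": self.var_frac,
            "explained_var_ratio": self.explained_var_ratio,
        }
        np.savez(
            path,
            mean_shape=self.mean_shape,
            components=self.components,
            eigenvalues=self.eigenvalues,
            m_oa=self.m_oa,
            m_non_oa=self.m_non_oa,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "ShapeVectorResults":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            return cls(
                bone=meta["bone"],
                n_points=int(meta["n_points"]),
                mean_shape=z["mean_shape"],
                components=z["components"],
                eigenvalues=z["eigenvalues"],
                m_oa=z["m_oa"],
                m_non_oa=z["m_non_oa"],
                n_train_oa=int(meta["n_train_oa"]),
                n_train_non_oa=int(meta["n_train_non_oa"]),
                var_frac=float(meta["var_frac"]),
                explained_var_ratio=float(meta["explained_var_ratio"]),
            )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"OA shape vector model: {self.bone}",
            f"  training shapes: {self.n_train_oa} OA / {self.n_train_non_oa} non-OA",
            f"  points per shape: {self.n_points}",
            f"  components retained: {self.components.shape[0]} "
            f"({100 * self.explained_var_ratio:.1f}% variance, target "
            f"{100 * self.var_frac:.0f}%)",
            f"  |m_OA - m_nonOA| = {np.linalg.norm(self.m_oa - self.m_non_oa):.3f} mm",
        ]
        return "\n".join(lines)

    def plot_vector_mode(self, ax=None, scale: float = 1.0):
        """Scatter the mean shape coloured by OA-vector displacement magnitude."""
        import matplotlib.pyplot as plt

        disp = ((self.m_oa - self.m_non_oa) @ self.components).reshape(-1, 3)
        mag = np.linalg.norm(disp, axis=1) * scale
        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        pts = self.mean_shape
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], c=mag, s=8)
        ax.set_title(f"{self.bone}: OA vector displacement (mm)")
        return ax
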
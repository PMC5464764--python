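"""Rigid (6-DOF) surface alignment: whole-surface ICP and generalized Procrustes.

All alignment here is strictly rotation + translation; size is never
altered, because the morphology classes of interest (long / short roots)
are themselves size differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .correspondence import PointDistributionModel
from .geometry_io import TriangleMesh

__all__ = ["RigidTransform", "icp_rigid", "generalized_procrustes", "align_cohort"]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    rms: float = np.nan
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthogonal (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])


def _points_of(shape) -> np.ndarray:
    if isinstance(shape, TriangleMesh):
        return shape.vertices
    if isinstance(shape, PointDistributionModel):
        return shape.points
    return np.asarray(shape, dtype=np.float64).reshape(-1, 3)


def _kabsch(moving, fixed, weights=None):
    from ._geom import kabsch

    return kabsch(moving, fixed, weights=weights)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt


def icp_rigid(
    moving,
    fixed,
    max_iterations: int = 100,
    tolerance: float = 1e-4,
    apex_hint=None,
    init: str = "pca",
    trim: float = 1.0,
    robust_scale: float | None = None,
) -> RigidTransform:
    """Whole-surface rigid best fit of ``moving`` onto ``fixed``.

    Point-to-point iterative closest point over all points, initialized by
    centroid + principal-axes alignment; the axis sign ambiguity is resolved
    by trying every proper sign combination (or the apex hint when given)
    and keeping the lowest starting residual, which avoids the 180-degree
    flip local minimum of elongated teeth.  ``init='identity'`` starts from
    the current pose instead (for shapes already roughly aligned, where a
    near-symmetric cross-section would make the PCA flip search ambiguous).
    Converged when the RMS closest-point distance changes by less than
    ``tolerance`` mm.
    """
    mv = _points_of(moving)
    fx = _points_of(fixed)
    if len(mv) < 3 or len(fx) < 3:
        raise ValueError("both shapes need at least 3 points")
    tree = cKDTree(fx)

    if init == "identity":
        R, t = np.eye(3), np.zeros(3)
        d, _ = tree.query(mv)
        rms0 = float(np.sqrt(np.mean(d**2)))
    else:
        am = _principal_axes(mv)
        af = _principal_axes(fx)
        candidates = []
        for s1, s2 in itertools.product((1, -1), repeat=2):
            s3 = s1 * s2  # keep det = +1
            R = af.T @ np.diag([s1, s2, s3]) @ am
            if apex_hint is not None:
                hint = np.asarray(apex_hint, dtype=np.float64)
                if float((R @ hint) @ hint) < 0:
                    continue
            t = fx.mean(axis=0) - R @ mv.mean(axis=0)
            d, _ = tree.query(mv @ R.T + t)
            candidates.append((float(np.sqrt(np.mean(d**2))), R, t))
        rms0, R, t = min(candidates, key=lambda c: c[0])

    if not (0.0 < trim <= 1.0):
        raise ValueError("trim must lie in (0, 1]")
    rms_prev = rms0
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        cur = mv @ R.T + t
        d, idx = tree.query(cur)
        if robust_scale is not None:
            # Cauchy weights: mismatching regions (true shape differences)
            # are down-weighted continuously and symmetrically, without the
            # budget competition of a hard trim
            w = 1.0 / (1.0 + (d / robust_scale) ** 2)
            dR, dt = _kabsch(cur, fx[idx], weights=w)
        elif trim < 1.0:
            # robust refinement: update the pose from the best-matching
            # fraction so genuine shape differences do not drag the fit
            keep = d <= np.quantile(d, trim)
            dR, dt = _kabsch(cur[keep], fx[idx[keep]])
        else:
            dR, dt = _kabsch(cur, fx[idx])
        R = dR @ R
        t = dR @ t + dt
        d, _ = tree.query(mv @ R.T + t)
        rms = float(np.sqrt(np.mean(d**2)))
        if abs(rms_prev - rms) < tolerance:
            converged = True
            rms_prev = rms
            break
        rms_prev = rms
    if not converged:
        warnings.warn("ICP did not converge; returning best transform", stacklevel=2)
    return RigidTransform(R, t, rms=rms_prev, converged=converged, n_iterations=it)


def generalized_procrustes(
    pdms: list[PointDistributionModel],
    max_iterations: int = 100,
    tolerance: float = 1e-6,
):
    """Rigid generalized Procrustes superimposition of homologous point sets.

    Rotation + translation only (no scaling); each shape is aligned to the
    evolving consensus until the consensus moves by less than ``tolerance``
    mm; the consensus centroid sits at the origin.

    Returns (aligned copies, consensus PDM).
    """
    if len(pdms) < 2:
        raise ValueError("generalized Procrustes needs at least 2 shapes")
    n_pts = {p.n_points for p in pdms}
    if len(n_pts) != 1:
        raise ValueError("mismatched point counts across PDMs")
    X = np.stack([p.points for p in pdms]).astype(np.float64)
    X -= X.mean(axis=1, keepdims=True)
    consensus = X[0].copy()
    consensus -= consensus.mean(axis=0)
    for _ in range(max_iterations):
        for i in range(len(X)):
            R, t = _kabsch(X[i], consensus)
            X[i] = X[i] @ R.T + t
        new_consensus = X.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_consensus - consensus, axis=1)))
        consensus = new_consensus
        if shift < tolerance:
            break
    aligned = []
    for p, pts in zip(pdms, X):
        q = p.copy()
        q.points = pts
        aligned.append(q)
    cons = pdms[0].copy()
    cons.points = consensus
    cons.tooth_id = "consensus"
    return aligned, cons


def align_cohort(
    pdms: list[PointDistributionModel],
    method: str = "icp",
    rounds: int = 3,
    robust_scale: float = 0.5,
):
    """Place a PDM cohort in a common coordinate system.

    ``method='gpa'`` is homologous-point generalized Procrustes.
    ``method='icp'`` (default for the pipeline) first coarse-aligns by
    homologous Procrustes (point identity breaks the azimuthal
    near-symmetry of incisor cross-sections), then refines each tooth
    against the evolving consensus by whole-surface closest-point best
    fit; with similar crowns across subgroups this anchors the common
    frame on the shared surface and lets root effects appear at the root.
    Returns (aligned copies, consensus).
    """
    if method == "gpa":
        return generalized_procrustes(pdms)
    if method != "icp":
        raise ValueError("method must be 'icp' or 'gpa'")
    if len(pdms) < 2:
        raise ValueError("cohort alignment needs at least 2 shapes")
    coarse, _ = generalized_procrustes(pdms)
    X = np.stack([p.points for p in coarse]).astype(np.float64)
    # the refinement target is the pointwise MEDIAN: a robust central shape
    # that typical teeth match exactly, so their pose is not dragged by the
    # subgroup composition (a mean consensus averages e.g. long and short
    # roots into a shape nobody matches, and every group absorbs part of
    # the length difference as a pose shift)
    consensus = np.median(X, axis=0)
    for _ in range(rounds):
        for i in range(len(X)):
            tf = icp_rigid(
                X[i], consensus, init="identity", robust_scale=robust_scale
            )
            X[i] = tf.apply(X[i])
        consensus = np.median(X, axis=0)
    aligned = []
    for p, pts in zip(pdms, X):
        q = p.copy()
        q.points = pts
        aligned.append(q)
    cons = pdms[0].copy()
    cons.points = consensus
    cons.tooth_id = "consensus"
    return aligned, cons
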
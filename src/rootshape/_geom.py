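"""Low-level geometric queries shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point to ``p`` on each triangle ``(a, b, c)``, all (N, 3).

    Branchless region test ("Real-Time Collision Detection", Ericson).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def _set(mask, value):
        nonlocal done
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done |= m

    _set((d1 <= 0) & (d2 <= 0), a)  # vertex A
    _set((d3 >= 0) & (d4 <= d3), b)  # vertex B
    _set((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    _set((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    _set((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    _set((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))  # edge BC

    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    interior = a + v[:, None] * ab + w[:, None] * ac
    out[~done] = interior[~done]
    return out


class SurfaceDistanceQuery:
    """Exact point-to-surface distances with KD-tree candidate pruning."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]  # (F, 3, 3)
        self._centroid_tree = cKDTree(self.tri.mean(axis=1))
        fn = np.cross(
            self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0]
        )
        self.face_normals = fn / np.maximum(
            np.linalg.norm(fn, axis=1, keepdims=True), 1e-300
        )

    def query(self, points: np.ndarray, k: int = 16):
        """Return (distance, closest point, face index) per query point."""
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        k = min(k, len(self.tri))
        _, cand = self._centroid_tree.query(points, k=k)
        cand = cand.reshape(len(points), -1)
        best_d = np.full(len(points), np.inf)
        best_cp = np.zeros_like(points)
        best_f = np.zeros(len(points), dtype=np.int64)
        for col in range(cand.shape[1]):
            fidx = cand[:, col]
            t = self.tri[fidx]
            cp = closest_point_on_triangles(points, t[:, 0], t[:, 1], t[:, 2])
            d = np.linalg.norm(points - cp, axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_cp[better] = cp[better]
            best_f[better] = fidx[better]
        return best_d, best_cp, best_f

    def signed_query(self, points: np.ndarray, k: int = 16):
        """Distances signed by the closest face's outward normal (+ = outside)."""
        d, cp, fidx = self.query(points, k=k)
        side = np.einsum(
            "ij,ij->i", np.asarray(points, dtype=np.float64) - cp,
            self.face_normals[fidx],
        )
        return d * np.where(side >= 0, 1.0, -1.0), cp, fidx


def kabsch(moving: np.ndarray, fixed: np.ndarray, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R, translation t minimizing ||R @ moving + t - fixed||."""
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if weights is None:
        mu_m = moving.mean(axis=0)
        mu_f = fixed.mean(axis=0)
        H = (moving - mu_m).T @ (fixed - mu_f)
    else:
        w = np.asarray(weights, dtype=np.float64)[:, None] / np.sum(weights)
        mu_m = (moving * w).sum(axis=0)
        mu_f = (fixed * w).sum(axis=0)
        H = (moving - mu_m).T @ ((fixed - mu_f) * w)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = mu_f - R @ mu_m
    return R, t
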
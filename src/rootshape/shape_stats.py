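"""Vertexwise two-group shape statistics: Hotelling's T2, permutation p-values
and false-discovery-rate control.

At each of the homologous surface points, the two cohorts' 3D coordinates
are compared with the two-sample Hotelling T2 statistic.  Significance is
assessed by permuting group labels of whole teeth (one relabeling applies
jointly to every point, preserving the spatial correlation of the surface),
exhaustively when the number of distinct relabelings is small enough.  The
resulting raw p-values are corrected with the Benjamini-Hochberg step-up
procedure at q = 0.05 over all sampled points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests

from .correspondence import PointDistributionModel
from .geometry_io import TriangleMesh
from .morphometry import diverging_rgb

__all__ = [
    "VertexStatResult",
    "hotelling_t2",
    "hotelling_t2_map",
    "permutation_test",
    "fdr_bh",
    "compare_groups",
    "significance_maps",
]


@dataclass
class VertexStatResult:
    """Per-point statistics of one subgroup-vs-reference comparison."""

    t2: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    mask: np.ndarray  # significant at q
    q: float
    n_permutations: int
    seed: int | None
    exact: bool  # exhaustive enumeration used instead of Monte Carlo


def _as_group_array(group) -> np.ndarray:
    """(n_subjects, n_points, 3) float array from PDMs or an array."""
    if isinstance(group, np.ndarray):
        arr = group.astype(np.float64, copy=False)
    else:
        arr = np.stack([
            g.points if isinstance(g, PointDistributionModel) else np.asarray(g)
            for g in group
        ]).astype(np.float64)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("groups must be (n_subjects, n_points, 3)")
    return arr


def _inv3(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched closed-form 3x3 inverse; returns (inverse, determinant)."""
    a, b, c = S[..., 0, 0], S[..., 0, 1], S[..., 0, 2]
    d, e, f = S[..., 1, 1], S[..., 1, 2], S[..., 2, 2]
    A = d * f - e * e
    B = c * e - b * f
    C = b * e - c * d
    det = a * A + b * B + c * C
    inv = np.empty_like(S)
    inv[..., 0, 0] = A
    inv[..., 0, 1] = inv[..., 1, 0] = B
    inv[..., 0, 2] = inv[..., 2, 0] = C
    inv[..., 1, 1] = a * f - c * c
    inv[..., 1, 2] = inv[..., 2, 1] = b * c - a * e
    inv[..., 2, 2] = a * d - b * b
    safe = np.where(det == 0, 1.0, det)
    return inv / safe[..., None, None], det


def _regularize(W: np.ndarray) -> np.ndarray:
    """Add lambda*I where the pooled scatter is near-singular."""
    tr = np.trace(W, axis1=-2, axis2=-1)
    # cheap near-singularity guard: lambda_min < 1e-10 tr implies
    # det < 1e-10 tr * (tr/2)^2, so flagging det below that bound is a
    # superset of the smallest-eigenvalue rule
    _, det = _inv3(W)
    bad = (det <= 2.5e-11 * np.maximum(tr, 0.0) ** 3) | (det <= 0)
    if np.any(bad):
        lam = 1e-8 * np.maximum(tr, 1e-300) / 3.0
        W = W + bad[..., None, None] * lam[..., None, None] * np.eye(3)
    return W


def hotelling_t2_map(XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
    """Two-sample Hotelling T2 at every point; groups (nA, P, 3), (nB, P, 3)."""
    XA, XB = _as_group_array(XA), _as_group_array(XB)
    nA, nB = len(XA), len(XB)
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 subjects")
    mA = XA.mean(axis=0)
    mB = XB.mean(axis=0)
    dA = XA - mA
    dB = XB - mB
    W = np.einsum("npi,npj->pij", dA, dA) + np.einsum("npi,npj->pij", dB, dB)
    W = _regularize(W)
    Winv, _ = _inv3(W)
    delta = mA - mB
    quad = np.einsum("pi,pij,pj->p", delta, Winv, delta)
    c = nA * nB / (nA + nB)
    return c * (nA + nB - 2) * quad


def hotelling_t2(groupA, groupB, point_index: int | None = None):
    """Two-sample Hotelling T2 on the 3D coordinates at one point.

    T2 = (nA nB / (nA + nB)) (xbarA - xbarB)' S_pooled^-1 (xbarA - xbarB),
    with the pooled covariance regularized by lambda I
    (lambda = 1e-8 trace(S)/3) when its smallest eigenvalue falls below
    1e-10 trace(S).
    """
    XA, XB = _as_group_array(groupA), _as_group_array(groupB)
    nA, nB = len(XA), len(XB)
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 subjects")
    if point_index is None:
        return hotelling_t2_map(XA, XB)
    a = XA[:, point_index]
    b = XB[:, point_index]
    delta = a.mean(axis=0) - b.mean(axis=0)
    W = np.cov(a.T, bias=False) * (nA - 1) + np.cov(b.T, bias=False) * (nB - 1)
    S = W / (nA + nB - 2)
    eigvals = np.linalg.eigvalsh(S)
    tr = float(np.trace(S))
    if eigvals[0] < 1e-10 * tr:
        S = S + (1e-8 * tr / 3.0) * np.eye(3)
    quad = float(delta @ np.linalg.solve(S, delta))
    return (nA * nB / (nA + nB)) * quad


def _t2_for_selections(X: np.ndarray, sel: np.ndarray, nA: int) -> np.ndarray:
    """T2 maps for many relabelings at once.

    ``X`` is (n, P, 3); ``sel`` is (B, n) with exactly nA ones per row.
    Uses the two-group scatter identity W = T_total - c delta delta' so each
    relabeling only needs the group-A mean.
    """
    n, P, _ = X.shape
    nB = n - nA
    grand = X.mean(axis=0)
    dX = X - grand
    T_total = np.einsum("npi,npj->pij", dX, dX)
    flat = X.reshape(n, P * 3)
    mA = (sel @ flat) / nA
    mA = mA.reshape(len(sel), P, 3)
    delta = (n / nB) * (mA - grand)
    c = nA * nB / n
    W = T_total[None] - c * np.einsum("bpi,bpj->bpij", delta, delta)
    W = _regularize(W)
    Winv, _ = _inv3(W)
    quad = np.einsum("bpi,bpij,bpj->bp", delta, Winv, delta)
    return c * (n - 2) * quad


def permutation_test(
    groupA,
    groupB,
    n_perm: int = 10000,
    seed: int | None = None,
    batch: int = 256,
):
    """Per-point raw permutation p-values for the Hotelling T2 map.

    One permutation relabels whole subjects jointly across all points.
    Monte Carlo p = (1 + #{T2_perm >= T2_obs}) / (1 + n_perm); when the
    number of distinct relabelings is <= n_perm the full enumeration is
    used instead (p = #{>=} / n_total, observed labeling included) and the
    result is flagged exact.

    Returns (p_raw, t2_obs, exact).
    """
    XA, XB = _as_group_array(groupA), _as_group_array(groupB)
    nA, nB = len(XA), len(XB)
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.concatenate([XA, XB], axis=0)
    n = nA + nB
    t2_obs = hotelling_t2_map(XA, XB)

    n_total = comb(n, nA)
    exact = n_total <= n_perm
    count = np.zeros(X.shape[1])
    if exact:
        combos = itertools.combinations(range(n), nA)
        rows = np.fromiter(
            (i for combo in combos for i in combo), dtype=np.int64
        ).reshape(n_total, nA)
        sel = np.zeros((n_total, n))
        sel[np.arange(n_total)[:, None], rows] = 1.0
        tol = 1e-9 * (1.0 + np.abs(t2_obs))  # ties (e.g. the complement
        # relabeling at equal group sizes) must count as >= despite float
        # differences between computation paths
        for start in range(0, n_total, batch):
            t2 = _t2_for_selections(X, sel[start:start + batch], nA)
            count += (t2 >= t2_obs - tol).sum(axis=0)
        p = count / n_total
    else:
        rng = np.random.default_rng(seed)
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            sel = np.zeros((b, n))
            for r in range(b):
                sel[r, rng.choice(n, size=nA, replace=False)] = 1.0
            t2 = _t2_for_selections(X, sel, nA)
            tol = 1e-9 * (1.0 + np.abs(t2_obs))
            count += (t2 >= t2_obs - tol).sum(axis=0)
            done += b
        p = (1.0 + count) / (1.0 + n_perm)
    return p, t2_obs, exact


def fdr_bh(p_raw: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask at q)."""
    p_raw = np.asarray(p_raw, dtype=np.float64)
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")
    return p_adj, reject


def compare_groups(
    groupA,
    groupB,
    n_perm: int = 10000,
    seed: int | None = None,
    q: float = 0.05,
) -> VertexStatResult:
    """Full vertexwise comparison: T2, permutation p, BH-FDR mask."""
    p_raw, t2_obs, exact = permutation_test(groupA, groupB, n_perm=n_perm, seed=seed)
    p_fdr, mask = fdr_bh(p_raw, q=q)
    return VertexStatResult(
        t2=t2_obs, p_raw=p_raw, p_fdr=p_fdr, mask=mask, q=q,
        n_permutations=n_perm, seed=seed, exact=exact,
    )


def significance_maps(
    result: VertexStatResult,
    shape: PointDistributionModel | TriangleMesh,
    alpha: float = 0.05,
) -> dict[str, TriangleMesh]:
    """Raw-p and FDR-corrected overlays with thresholded colors.

    Significant points are colored by -log10(p) intensity; non-significant
    points stay neutral gray.  All scalar channels (``t2``, ``p_raw``,
    ``p_fdr``, ``sig_mask``) are stored alongside the colors.
    """
    mesh = shape.to_mesh() if isinstance(shape, PointDistributionModel) else shape.copy()
    out = {}
    for kind, p, sig in (
        ("raw", result.p_raw, result.p_raw <= alpha),
        ("fdr", result.p_fdr, result.mask),
    ):
        m = mesh.copy()
        m.point_data["t2"] = result.t2
        m.point_data["p_raw"] = result.p_raw
        m.point_data["p_fdr"] = result.p_fdr
        m.point_data["sig_mask"] = result.mask.astype(np.uint8)
        colors = np.full((mesh.n_vertices, 3), 220, dtype=np.uint8)  # neutral
        if sig.any():
            intensity = -np.log10(np.maximum(p[sig], 1e-12))
            scaled = np.clip(intensity / max(intensity.max(), 1e-12), 0.2, 1.0)
            colors[sig] = diverging_rgb(scaled, 1.0)
        m.point_data["rgb"] = colors
        out[kind] = m
    return out
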
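"""Homologous surface points via spherical parameterization and SPHARM fitting.

A genus-0 tooth surface is mapped to the unit sphere (harmonic latitude with
area equalization, harmonic longitude around a pole-to-pole cut), each
coordinate channel is expanded in real spherical harmonics, the parameter
sphere is rotated into a canonical frame defined by the first-degree
ellipsoid, and the surface is resampled at the vertices of a subdivided
icosahedron.  At subdivision level ``n`` this yields ``10 n^2 + 2`` ordered
points — 1002 at the default level 10 — whose ordering is identical for every
tooth processed the same way, which is what makes pointwise cohort statistics
meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.special import sph_harm_y

from .geometry_io import TriangleMesh

__all__ = [
    "SphericalMap",
    "SPHARMCoefficients",
    "PointDistributionModel",
    "spherical_parameterization",
    "fit_spharm",
    "canonicalize_parameterization",
    "icosphere_sampling",
    "icosphere_faces",
    "evaluate_pdm",
    "correspond",
    "read_pdm",
    "write_pdm",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SphericalMap:
    """Unit-sphere coordinates (theta in [0, pi], phi in [0, 2pi)) per vertex."""

    theta: np.ndarray
    phi: np.ndarray
    north: int
    south: int

    @property
    def unit_directions(self) -> np.ndarray:
        st = np.sin(self.theta)
        return np.column_stack(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )

    def flipped_triangles(self, faces: np.ndarray) -> np.ndarray:
        return _flipped_mask(self.unit_directions, faces)


@dataclass
class SPHARMCoefficients:
    """Real spherical-harmonic coefficients of the x, y, z coordinate channels."""

    max_degree: int
    coeffs: np.ndarray  # ((L+1)^2, 3)
    rms_residual: float = np.nan

    def __post_init__(self) -> None:
        expected = (self.max_degree + 1) ** 2
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64).reshape(expected, 3)

    def evaluate(self, directions: np.ndarray, max_degree: int | None = None) -> np.ndarray:
        """Evaluate the SPHARM surface at unit directions, (N, 3) mm."""
        L = self.max_degree if max_degree is None else min(max_degree, self.max_degree)
        theta, phi = _dirs_to_angles(directions)
        basis = real_sph_harm_basis(L, theta, phi)
        return basis @ self.coeffs[: (L + 1) ** 2]

    def degree_energy(self) -> np.ndarray:
        """Summed squared coefficient norm per degree l (spectral profile)."""
        out = np.zeros(self.max_degree + 1)
        for l in range(self.max_degree + 1):
            block = self.coeffs[l * l:(l + 1) * (l + 1)]
            out[l] = float(np.sum(block**2))
        return out


@dataclass
class PointDistributionModel:
    """Ordered homologous surface points shared across a cohort."""

    points: np.ndarray  # (10 n^2 + 2, 3) mm
    level: int
    tooth_id: str = ""
    tooth_type: str = "central"  # central | lateral
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        expected = 10 * self.level**2 + 2
        if len(self.points) != expected:
            raise ValueError(
                f"level-{self.level} sampling requires {expected} points, "
                f"got {len(self.points)}"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    def faces(self) -> np.ndarray:
        return icosphere_faces(self.level)

    def to_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.points.copy(), self.faces())

    def copy(self) -> "PointDistributionModel":
        return PointDistributionModel(
            self.points.copy(), self.level, self.tooth_id, self.tooth_type,
            dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# icosahedral sampling (deterministic ordering is part of the file contract)
# ---------------------------------------------------------------------------

_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=np.float64,
)
_ICO_VERTS /= np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def _geodesic_icosahedron(level: int):
    """Frequency-``level`` geodesic subdivision with a fixed, reproducible order.

    Vertex order: the 12 base vertices, then the interior points of the 30
    unique edges (edges sorted lexicographically, points walked from the
    lower to the higher base index), then the interior lattice points of the
    20 faces in base-face order.
    """
    n = int(level)
    if n < 1:
        raise ValueError("subdivision level must be >= 1")
    verts = [v for v in _ICO_VERTS]
    edge_start: dict[tuple[int, int], int] = {}
    edges = sorted(
        {tuple(sorted((f[i], f[(i + 1) % 3]))) for f in _ICO_FACES for i in range(3)}
    )
    for (i, j) in edges:
        edge_start[(i, j)] = len(verts)
        for t in range(1, n):
            p = (1 - t / n) * _ICO_VERTS[i] + (t / n) * _ICO_VERTS[j]
            verts.append(p / np.linalg.norm(p))

    def edge_point(i, j, t):
        # t in 1..n-1 measured from i toward j
        if i < j:
            return edge_start[(i, j)] + (t - 1)
        return edge_start[(j, i)] + (n - t - 1)

    faces_out = []
    for (a, b, c) in _ICO_FACES:
        # lattice L[i][j]: barycentric (n-i-j, i, j) over corners (a, b, c)
        L = {}
        L[(0, 0)] = a
        L[(n, 0)] = b
        L[(0, n)] = c
        for t in range(1, n):
            L[(t, 0)] = edge_point(a, b, t)
            L[(0, t)] = edge_point(a, c, t)
            L[(n - t, t)] = edge_point(b, c, t)
        for i in range(1, n):
            for j in range(1, n - i):
                L[(i, j)] = len(verts)
                p = (
                    (n - i - j) * _ICO_VERTS[a]
                    + i * _ICO_VERTS[b]
                    + j * _ICO_VERTS[c]
                ) / n
                verts.append(p / np.linalg.norm(p))
        for i in range(n):
            for j in range(n - i):
                faces_out.append((L[(i, j)], L[(i + 1, j)], L[(i, j + 1)]))
                if i + j < n - 1:
                    faces_out.append((L[(i + 1, j)], L[(i + 1, j + 1)], L[(i, j + 1)]))
    return np.array(verts), np.array(faces_out, dtype=np.int64)


def icosphere_sampling(level: int) -> np.ndarray:
    """Ordered unit directions of the subdivided icosahedron (10 level^2 + 2)."""
    verts, _ = _geodesic_icosahedron(level)
    return verts


def icosphere_faces(level: int) -> np.ndarray:
    """Triangle list matching :func:`icosphere_sampling`'s vertex order."""
    _, faces = _geodesic_icosahedron(level)
    return faces


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------

def real_sph_harm_basis(L: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Design matrix of real spherical harmonics, columns indexed l^2 + l + m."""
    theta = np.asarray(theta, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    cols = np.empty((len(theta), (L + 1) ** 2))
    sqrt2 = np.sqrt(2.0)
    for l in range(L + 1):
        y0 = sph_harm_y(l, 0, theta, phi)
        cols[:, l * l + l] = y0.real
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            sign = (-1.0) ** m
            cols[:, l * l + l + m] = sqrt2 * sign * y.real
            cols[:, l * l + l - m] = sqrt2 * sign * y.imag
    return cols


def _dirs_to_angles(directions: np.ndarray):
    d = np.asarray(directions, dtype=np.float64).reshape(-1, 3)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(d[:, 1], d[:, 0]), TWO_PI)
    return theta, phi


# ---------------------------------------------------------------------------
# spherical parameterization
# ---------------------------------------------------------------------------

def _cotan_laplacian(v: np.ndarray, f: np.ndarray) -> sparse.csr_matrix:
    """Positive semidefinite cotangent Laplacian, weights clamped >= 1e-6."""
    ii, jj, ww = [], [], []
    for corner, (a, b) in (((0), (1, 2)), ((1), (2, 0)), ((2), (0, 1))):
        e1 = v[f[:, a]] - v[f[:, corner]]
        e2 = v[f[:, b]] - v[f[:, corner]]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-300)
        w = np.maximum(0.5 * cot, 1e-6)
        ii.append(f[:, a]); jj.append(f[:, b]); ww.append(w)
        ii.append(f[:, b]); jj.append(f[:, a]); ww.append(w)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    w = np.concatenate(ww)
    W = sparse.coo_matrix((w, (i, j)), shape=(len(v), len(v))).tocsr()
    return sparse.diags(np.asarray(W.sum(axis=1)).ravel()) - W


def _vertex_areas(v: np.ndarray, f: np.ndarray) -> np.ndarray:
    fa = 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
    )
    out = np.zeros(len(v))
    for c in range(3):
        np.add.at(out, f[:, c], fa / 3.0)
    return out


def _solve_dirichlet(L: sparse.csr_matrix, fixed_idx, fixed_val) -> np.ndarray:
    n = L.shape[0]
    fixed_idx = np.asarray(fixed_idx)
    fixed_val = np.asarray(fixed_val, dtype=np.float64)
    free = np.setdiff1d(np.arange(n), fixed_idx)
    x = np.zeros(n)
    x[fixed_idx] = fixed_val
    A = L[free][:, free].tocsc()
    b = -L[free][:, fixed_idx] @ fixed_val
    x[free] = sparse.linalg.spsolve(A, b)
    return x


def _ordered_one_ring(vertex: int, faces_of_vertex: np.ndarray, faces: np.ndarray):
    """Neighbours of ``vertex`` in the cyclic order induced by face orientation."""
    succ = {}
    for fi in faces_of_vertex:
        tri = faces[fi]
        k = int(np.where(tri == vertex)[0][0])
        succ[int(tri[(k + 1) % 3])] = int(tri[(k + 2) % 3])
    start = next(iter(succ))
    ring = [start]
    while True:
        nxt = succ[ring[-1]]
        if nxt == start:
            break
        ring.append(nxt)
        if len(ring) > len(succ) + 1:
            raise ValueError("non-manifold vertex star")
    return ring


def _flipped_mask(s: np.ndarray, faces: np.ndarray) -> np.ndarray:
    det = np.einsum(
        "ij,ij->i", s[faces[:, 0]], np.cross(s[faces[:, 1]], s[faces[:, 2]])
    )
    return det <= 1e-12


def spherical_parameterization(
    mesh: TriangleMesh,
    max_relax_iterations: int = 2000,
    cut_direction=None,
    axis_hint=None,
) -> SphericalMap:
    """Map a watertight genus-0 mesh bijectively onto the unit sphere.

    Poles are the extremal vertices along the first principal axis.
    Latitude is the harmonic (discrete Laplace) interpolation between the
    poles, re-graded so that surface area accumulates like spherical-cap
    area (plain harmonic latitude with point poles degenerates toward the
    equator).  Longitude is a harmonic cyclic field around the pole axis,
    realized by cutting the mesh along a pole-to-pole path and imposing a
    2*pi jump across the cut.  Local tangential relaxation is applied until
    no spherical triangle is flipped.
    """
    if not mesh.is_watertight() or mesh.euler_characteristic() != 2:
        raise ValueError("surface not sphere-topology (watertight genus-0 required)")
    v, f = mesh.vertices, mesh.faces
    centred = v - v.mean(axis=0)
    if axis_hint is not None:
        axis = np.asarray(axis_hint, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
    else:
        _, _, Vt = np.linalg.svd(centred, full_matrices=False)
        axis = Vt[0]
    proj = centred @ axis

    def _pole(sign: float) -> int:
        # among vertices within 0.5 mm of the extreme along the axis, take
        # the most central one: the raw argmax wanders along flat end
        # ridges under segmentation noise
        p = sign * proj
        cand = np.where(p >= p.max() - 0.5)[0]
        lateral = centred[cand] - np.outer(centred[cand] @ axis, axis)
        centre = lateral.mean(axis=0)
        return int(cand[np.argmin(np.linalg.norm(lateral - centre, axis=1))])

    north, south = _pole(1.0), _pole(-1.0)

    L = _cotan_laplacian(v, f)
    u = _solve_dirichlet(L, [north, south], [0.0, 1.0])

    # area-equalized latitude: theta such that area below u matches cap area;
    # the empirical area CDF is smoothed over quantile knots so that vertices
    # on the same level set share the same latitude
    areas = _vertex_areas(v, f)
    order = np.argsort(u)
    cum = np.cumsum(areas[order]) - 0.5 * areas[order]
    frac_sorted = cum / areas.sum()
    u_sorted = u[order]
    # knots uniform in target latitude (dense in area near the pole caps)
    n_knots = max(16, int(np.sqrt(len(v))))
    knot_theta = np.linspace(0.0, np.pi, n_knots)
    knot_frac = 0.5 * (1.0 - np.cos(knot_theta))
    knot_u = np.interp(knot_frac, frac_sorted, u_sorted)
    knot_u, uniq = np.unique(knot_u, return_index=True)
    theta = np.interp(u, knot_u, knot_theta[uniq])
    theta[north], theta[south] = 0.0, np.pi

    phi = _harmonic_longitude(v, f, L, north, south, cut_direction=cut_direction)

    st = np.sin(theta)
    s = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    s[north] = (0.0, 0.0, 1.0)
    s[south] = (0.0, 0.0, -1.0)
    # the cut-side convention fixes chirality arbitrarily; mirror if the map
    # came out with inverted handedness relative to the surface orientation
    if _flipped_mask(s, f).mean() > 0.5:
        s[:, 1] = -s[:, 1]
    s = _repair_flips(s, f, frozen=(north, south), max_iterations=max_relax_iterations)

    theta, phi = _dirs_to_angles(s)
    theta[north], phi[north] = 0.0, 0.0
    theta[south], phi[south] = np.pi, 0.0
    return SphericalMap(theta=theta, phi=phi, north=north, south=south)


def _harmonic_longitude(v, f, L, north, south, cut_direction=None) -> np.ndarray:
    n = len(v)
    # pole-to-pole path = the cut meridian (phi = 0 there); when a cut
    # direction is supplied the path is steered along that anatomical
    # half-plane so the (small) discretization distortion of the cut sits
    # at the same anatomical azimuth for every tooth
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    lengths = np.linalg.norm(v[rows] - v[cols], axis=1)
    if cut_direction is not None:
        centroid = v.mean(axis=0)
        axis = v[north] - v[south]
        axis = axis / np.linalg.norm(axis)
        cd = np.asarray(cut_direction, dtype=np.float64)
        cd = cd - (cd @ axis) * axis
        cd = cd / np.linalg.norm(cd)
        perp = np.cross(axis, cd)
        r = v - centroid
        penalty = np.abs(r @ perp) + np.maximum(0.0, -(r @ cd))
        lengths = lengths * (1.0 + 2.0 * (penalty[rows] + penalty[cols]))
    G = sparse.coo_matrix((lengths, (rows, cols)), shape=(n, n)).tocsr()
    _, pred = dijkstra(G, directed=False, indices=north, return_predecessors=True)
    path = [south]
    while path[-1] != north:
        p = pred[path[-1]]
        if p < 0:
            raise ValueError("mesh is disconnected")
        path.append(int(p))
    path = path[::-1]  # north ... south

    faces_of = [[] for _ in range(n)]
    for fi, tri in enumerate(f):
        for vert in tri:
            faces_of[vert].append(fi)

    # classify each neighbour of every interior path vertex as west (sees 0)
    # or east (sees 2*pi) using the oriented one-ring split by the path
    east_edges: set[tuple[int, int]] = set()
    for t in range(1, len(path) - 1):
        vt = path[t]
        prv, nxt = path[t - 1], path[t + 1]
        ring = _ordered_one_ring(vt, np.array(faces_of[vt]), f)
        i_prv, i_nxt = ring.index(prv), ring.index(nxt)
        k = len(ring)
        i = (i_nxt + 1) % k
        while i != i_prv:
            east_edges.add((ring[i], vt))
            i = (i + 1) % k

    on_path = np.zeros(n, dtype=bool)
    on_path[path] = True
    W = -L.copy()
    W.setdiag(0)
    W.eliminate_zeros()
    W = W.tocsr()

    free = np.where(~on_path)[0]
    pos = -np.ones(n, dtype=np.int64)
    pos[free] = np.arange(len(free))
    rowsA, colsA, valsA = [], [], []
    bvec = np.zeros(len(free))
    diag = np.zeros(len(free))
    Wc = W.tocoo()
    for i, j, w in zip(Wc.row, Wc.col, Wc.data):
        if on_path[i]:
            continue
        if j == north or j == south:
            continue  # poles carry no longitude: natural boundary
        diag[pos[i]] += w
        if on_path[j]:
            if (i, j) in east_edges:
                bvec[pos[i]] += w * TWO_PI
            # west side contributes 0
        else:
            rowsA.append(pos[i]); colsA.append(pos[j]); valsA.append(-w)
    A = sparse.coo_matrix(
        (np.concatenate([valsA, diag]),
         (np.concatenate([rowsA, np.arange(len(free))]),
          np.concatenate([colsA, np.arange(len(free))]))),
        shape=(len(free), len(free)),
    ).tocsc()
    phi = np.zeros(n)
    phi[free] = sparse.linalg.spsolve(A, bvec)
    return np.mod(phi, TWO_PI)


def _repair_flips(s, f, frozen, max_iterations) -> np.ndarray:
    s = s.copy()
    n = len(s)
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    adj.data[:] = 1.0
    frozen = np.asarray(frozen)
    for it in range(max_iterations):
        bad = _flipped_mask(s, f)
        if not bad.any():
            return s
        verts = np.unique(f[bad])
        if it > max_iterations // 4:
            # widen to the 2-ring when the 1-ring alone cannot untangle
            ring2 = np.unique(adj[verts].nonzero()[1])
            verts = np.union1d(verts, ring2)
        if it <= max_iterations // 2:
            verts = np.setdiff1d(verts, frozen)
        if verts.size == 0:
            break
        avg = adj[verts] @ s
        norms = np.linalg.norm(avg, axis=1, keepdims=True)
        ok = norms[:, 0] > 1e-12
        s[verts[ok]] = avg[ok] / norms[ok]
    bad = _flipped_mask(s, f)
    if bad.any():
        raise ValueError(
            f"spherical map still has {int(bad.sum())} flipped triangles "
            f"after {max_iterations} relaxation passes"
        )
    return s


# ---------------------------------------------------------------------------
# SPHARM fitting, canonicalization, evaluation
# ---------------------------------------------------------------------------

def fit_spharm(mesh: TriangleMesh, smap: SphericalMap, degree: int = 12) -> SPHARMCoefficients:
    """Least-squares real-SPHARM expansion of the coordinate channels."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n_basis = (degree + 1) ** 2
    if n_basis > mesh.n_vertices:
        raise ValueError(
            f"underdetermined SPHARM fit: {n_basis} basis functions for "
            f"{mesh.n_vertices} vertices"
        )
    basis = real_sph_harm_basis(degree, smap.theta, smap.phi)
    coeffs, _, _, _ = np.linalg.lstsq(basis, mesh.vertices, rcond=None)
    resid = mesh.vertices - basis @ coeffs
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SPHARMCoefficients(max_degree=degree, coeffs=coeffs, rms_residual=rms)


def first_order_ellipsoid(coeffs: SPHARMCoefficients) -> np.ndarray:
    """The 3x3 linear map M of the degree-1 surface term (u -> M u)."""
    block = coeffs.coeffs[1:4]  # rows: m = -1, 0, +1
    eye = np.eye(3)
    theta, phi = _dirs_to_angles(eye)
    basis1 = real_sph_harm_basis(1, theta, phi)[:, 1:4]
    return (basis1 @ block).T  # column k = degree-1 surface at e_k


def canonicalize_parameterization(
    coeffs: SPHARMCoefficients,
    apex_direction,
    mesiodistal_direction=None,
    refit_level: int = 16,
) -> SPHARMCoefficients:
    """Rotate parameter space into the canonical first-order frame.

    The degree-1 ellipsoid's longest axis is sent to the pole (theta) axis.
    The two-fold flip ambiguity is resolved by requiring the north pole to
    map toward the apex (crown-to-apex direction of the supplied tooth
    frame).  When a mesiodistal hint is given, phi = 0 is anchored to the
    parameter direction whose degree-1 image points mesially — anchoring
    the azimuth to anatomy keeps the correspondence consistent across
    morphology subgroups whose second ellipsoid axis switches identity
    (e.g. a lingual dilaceration inflates the faciolingual extent);
    without a hint the ellipsoid's second axis is used.
    """
    M = first_order_ellipsoid(coeffs)
    U, S, Vt = np.linalg.svd(M)
    if S[0] > 0 and (S[0] - S[1]) / S[0] < 1e-6:
        warnings.warn(
            "degenerate first-order ellipsoid; orientation taken from tooth frame",
            stacklevel=2,
        )
    apex = np.asarray(apex_direction, dtype=np.float64)
    apex = apex / np.linalg.norm(apex)
    z_col = Vt[0]
    if float((M @ z_col) @ apex) < 0:
        z_col = -z_col
    if mesiodistal_direction is not None:
        md = np.asarray(mesiodistal_direction, dtype=np.float64)
        md = md / np.linalg.norm(md)
        # anchor the azimuth on crown geometry: evaluate the surface on a
        # parameter ring at crown latitude (away from any apical bend) and
        # take the azimuth whose surface point projects furthest mesially
        e1 = np.cross(z_col, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(z_col, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(z_col, e1)
        az = np.linspace(0.0, TWO_PI, 720, endpoint=False)
        axis_surf = M @ z_col
        axis_surf = axis_surf / np.linalg.norm(axis_surf)
        # combine several crown latitudes (apex maps to the north pole, so
        # the crown is the southern hemisphere), each ring weighted by its
        # in-plane anisotropy: near-circular sections carry no azimuth
        # information and would otherwise inject noise
        accum = 0.0 + 0.0j
        for theta0 in np.radians([100.0, 115.0, 130.0, 145.0]):
            ring_dirs = (
                np.cos(theta0) * z_col[None, :]
                + np.sin(theta0)
                * (np.outer(np.cos(az), e1) + np.outer(np.sin(az), e2))
            )
            ring = coeffs.evaluate(ring_dirs)
            centred = ring - ring.mean(axis=0)
            lat = centred - np.outer(centred @ axis_surf, axis_surf)
            # robust in-plane orientation: second-moment major axis (an
            # integral quantity; a pointwise argmax is unstable on
            # flat-sided crowns)
            evals, evecs = np.linalg.eigh(lat.T @ lat)
            d_star = evecs[:, -1]
            if float(d_star @ md) < 0:
                d_star = -d_star
            anisotropy = float(evals[-1] - evals[-2])
            # parameter azimuth of d_star: phase of the fundamental Fourier
            # mode of the projection signal
            proj = lat @ d_star
            accum += anisotropy * np.exp(1j * np.angle(np.sum(proj * np.exp(1j * az))))
        phase = float(np.angle(accum))
        x_col = np.cos(phase) * e1 + np.sin(phase) * e2
    else:
        x_col = Vt[1]
        x_col = x_col - (x_col @ z_col) * z_col
        x_col /= np.linalg.norm(x_col)
    y_col = np.cross(z_col, x_col)
    R = np.column_stack([x_col, y_col, z_col])  # u = R v

    dirs = icosphere_sampling(refit_level)
    values = coeffs.evaluate(dirs @ R.T)
    theta, phi = _dirs_to_angles(dirs)
    basis = real_sph_harm_basis(coeffs.max_degree, theta, phi)
    new_coeffs, _, _, _ = np.linalg.lstsq(basis, values, rcond=None)
    return SPHARMCoefficients(
        max_degree=coeffs.max_degree,
        coeffs=new_coeffs,
        rms_residual=coeffs.rms_residual,
    )


def evaluate_pdm(
    coeffs: SPHARMCoefficients,
    level: int = 10,
    tooth_id: str = "",
    tooth_type: str = "central",
) -> PointDistributionModel:
    """Sample the SPHARM surface at the icosahedral directions (homologous order)."""
    dirs = icosphere_sampling(level)
    points = coeffs.evaluate(dirs)
    return PointDistributionModel(
        points=points, level=level, tooth_id=tooth_id, tooth_type=tooth_type
    )


def correspond(
    mesh: TriangleMesh,
    apex_direction,
    mesiodistal_direction=None,
    level: int = 10,
    degree: int = 12,
    tooth_id: str = "",
    tooth_type: str = "central",
) -> PointDistributionModel:
    """Full correspondence chain: parameterize, fit, canonicalize, sample."""
    # the cut meridian is steered facially: dilacerations in this taxonomy
    # bend mesially, distally or lingually, so the facial side is the
    # azimuth least likely to carry a bent apex into the cut's
    # discretization error
    cut_dir = None
    if mesiodistal_direction is not None:
        cut_dir = np.cross(apex_direction, mesiodistal_direction)
    smap = spherical_parameterization(
        mesh, cut_direction=cut_dir, axis_hint=apex_direction
    )
    coeffs = fit_spharm(mesh, smap, degree=degree)
    canon = canonicalize_parameterization(
        coeffs, apex_direction, mesiodistal_direction
    )
    pdm = evaluate_pdm(canon, level=level, tooth_id=tooth_id, tooth_type=tooth_type)
    pdm.metadata["spharm_rms_residual"] = coeffs.rms_residual
    return pdm


# ---------------------------------------------------------------------------
# PDM text I/O: "n=1002 level=10" header then one "x y z" row per point
# ---------------------------------------------------------------------------

def write_pdm(pdm: PointDistributionModel, path) -> Path:
    path = Path(path)
    lines = [f"n={pdm.n_points} level={pdm.level}"]
    lines += [
        f"{float(x)!r} {float(y)!r} {float(z)!r}" for x, y, z in pdm.points
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pdm(path, tooth_id: str = "", tooth_type: str = "central") -> PointDistributionModel:
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    header = dict(kv.split("=") for kv in lines[0].split())
    points = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
    return PointDistributionModel(
        points=points,
        level=int(header["level"]),
        tooth_id=tooth_id or path.stem,
        tooth_type=tooth_type,
    )
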
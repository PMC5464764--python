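"""Synthetic single-rooted incisor surfaces with known subgroup deformations.

The generator emulates a maxillary incisor as a stack of superelliptic
cross-sections along a centerline: a crown with rounded-rectangular sections
(superellipse exponent 4) tapering incisally, and a root with elliptical
sections tapering linearly to a spherical apex cap.  The centerline can be
bent beyond a chosen onset fraction of the root (dilaceration), and vertices
receive seeded radial Gaussian noise emulating segmentation roughness.

Generator frame (documented, used by tests and the pipeline):
apex at z = 0, cemento-enamel junction at z = root_length, incisal edge at
z = root_length + crown_height.  Crown-to-apex direction is -z, mesial is
+x, lingual is +y.

Every generated mesh is closed, genus 0 and consistently oriented outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry_io import TriangleMesh, vertex_normals

__all__ = [
    "ToothParams",
    "CohortSpec",
    "SUBGROUP_EFFECTS",
    "SUBGROUPS",
    "apply_subgroup_effect",
    "generate_tooth",
    "generate_cohort",
    "perturb_as_second_rater",
    "APEX_DIRECTION",
    "MESIAL_DIRECTION",
    "LINGUAL_DIRECTION",
]

APEX_DIRECTION = np.array([0.0, 0.0, -1.0])
MESIAL_DIRECTION = np.array([1.0, 0.0, 0.0])
LINGUAL_DIRECTION = np.array([0.0, 1.0, 0.0])

SUBGROUPS = (
    "neutral",
    "blunt",
    "long",
    "conical",
    "short",
    "mesial_dilaceration",
    "distal_dilaceration",
    "lingual_dilaceration",
)


@dataclass
class ToothParams:
    """Dimensions (mm) and noise settings of one synthetic incisor.

    Crown width default follows reported mean central-incisor crown widths
    (8.9 male / 8.7 female); the remaining dimensions are textbook-scale
    values for a maxillary central incisor, configurable throughout.
    """

    crown_height: float = 10.0
    crown_width_md: float = 8.8
    crown_thickness_fl: float = 7.0
    root_length: float = 13.0
    cervical_width_md: float = 6.5
    cervical_width_fl: float = 6.0
    apex_radius: float = 0.6
    bend_angle: float = 0.0  # degrees, in [0, 45]
    bend_direction: str = "distal"  # mesial | distal | lingual
    bend_onset: float = 0.67  # fraction of root length, measured from the CEJ
    root_width_delta: float = 0.0  # mm radial offset of the root profile
    root_width_scale: float = 1.0  # multiplicative root-profile scaling
    torsion_deg: float = 0.0  # axial twist apex->incisal (degrees)
    crown_taper_md: float = 0.22  # incisal narrowing of the crown (md)
    crown_taper_fl: float = 0.45  # incisal thinning of the crown (fl)
    crown_bulge: float = 0.45  # relative height of the widest crown level
    noise_sigma: float = 0.05  # mm
    seed: int = 0

    def validate(self) -> None:
        lengths = (
            self.crown_height, self.crown_width_md, self.crown_thickness_fl,
            self.root_length, self.cervical_width_md, self.cervical_width_fl,
            self.apex_radius,
        )
        if any(x <= 0 for x in lengths):
            raise ValueError("all tooth dimensions must be positive")
        if not (0.0 <= self.bend_angle <= 45.0):
            raise ValueError("bend_angle must lie in [0, 45] degrees")
        if self.bend_direction not in ("mesial", "distal", "lingual"):
            raise ValueError(f"unknown bend direction {self.bend_direction!r}")
        if not (0.0 < self.bend_onset < 1.0):
            raise ValueError("bend_onset must be a fraction of the root in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def total_length(self) -> float:
        return self.crown_height + self.root_length


# Effect presets express how each morphology subgroup deviates from neutral.
# Additive width deltas are radial surface offsets (each lateral surface
# moves outward by the stated amount); multiplicative entries scale the
# width parameters.
SUBGROUP_EFFECTS: dict[str, dict] = {
    "neutral": {},
    "long": {"root_length": ("+", 2.0), "root_radial": ("+", 0.3)},
    "conical": {"root_scale": ("*", 0.8)},
    "short": {"root_length": ("+", -2.0), "root_scale": ("*", 0.85)},
    "blunt": {
        "root_length": ("+", -1.5),
        "apex_radius": ("*", 2.5),
        "root_radial": ("+", 0.4),
    },
    "mesial_dilaceration": {"bend": ("mesial", 20.0)},
    "distal_dilaceration": {"bend": ("distal", 20.0)},
    "lingual_dilaceration": {"bend": ("lingual", 20.0)},
}


def apply_subgroup_effect(params: ToothParams, subgroup: str) -> ToothParams:
    """Return a copy of ``params`` with the subgroup's effect preset applied."""
    if subgroup not in SUBGROUP_EFFECTS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    p = replace(params)
    for key, spec in SUBGROUP_EFFECTS[subgroup].items():
        if key == "root_length":
            p.root_length += spec[1]
        elif key == "apex_radius":
            p.apex_radius *= spec[1]
        elif key == "root_radial":
            # each lateral root surface moves out by spec[1] mm
            p.root_width_delta += spec[1]
        elif key == "root_scale":
            p.root_width_scale *= spec[1]
        elif key == "bend":
            p.bend_direction, p.bend_angle = spec
        else:  # pragma: no cover
            raise KeyError(key)
    return p


#: per-tooth anatomical standard deviations (mm or relative), emulating
#: inter-subject variation; the crown-width SD follows reported population
#: values (~0.6 mm)
ANATOMICAL_SD = {
    "crown_width_md": 0.6,
    "crown_thickness_fl": 0.6,
    "crown_height": 0.8,
    "root_length": 1.2,
    "cervical_rel": 0.02,  # relative SD of cervical widths
    "apex_radius_rel": 0.10,
    "torsion_deg": 5.0,  # axial twist; rigid alignment cannot remove it
    "crown_taper_md": 0.05,  # incisal-edge shape variation (wear, mamelons)
    "crown_taper_fl": 0.10,
    "crown_bulge": 0.08,
    "surface_field": 0.25,  # smooth individual surface relief (mm)
}


@dataclass
class CohortSpec:
    """A cohort of one subgroup: shared template, independent per-tooth
    anatomy (sampled around the template) and surface noise."""

    subgroup: str = "neutral"
    n: int = 20
    seed: int = 0
    base_params: ToothParams = field(default_factory=ToothParams)
    anatomical_scale: float = 1.0  # 0 disables inter-subject variation

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.subgroup not in SUBGROUP_EFFECTS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")


# ---------------------------------------------------------------------------
# surface construction
# ---------------------------------------------------------------------------

_N_THETA = 48  # angular samples per cross-section ring


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _profile(params: ToothParams, z: np.ndarray):
    """Half-widths (a: mesiodistal, b: faciolingual) and superellipse
    exponent at each axial station z (apex at 0)."""
    Lr, Hc = params.root_length, params.crown_height
    ar = params.apex_radius
    ca, cb = params.cervical_width_md / 2, params.cervical_width_fl / 2
    Aa, Ab = params.crown_width_md / 2, params.crown_thickness_fl / 2
    a = np.empty_like(z)
    b = np.empty_like(z)
    p = np.full_like(z, 2.0)

    root = z <= Lr
    s = np.clip(z[root] / Lr, 0.0, 1.0)  # 0 at apex, 1 at CEJ
    a[root] = ar + (ca - ar) * s
    b[root] = ar + (cb - ar) * s
    # subgroup width effects act on the root only: faded to zero at the
    # CEJ (the crown is shared across subgroups) and at the apex cap
    if params.root_width_delta != 0.0 or params.root_width_scale != 1.0:
        w = _smoothstep(s / 0.15) * (1.0 - _smoothstep((s - 0.9) / 0.1))
        a[root] = a[root] * (1.0 + (params.root_width_scale - 1.0) * w) + params.root_width_delta * w
        b[root] = b[root] * (1.0 + (params.root_width_scale - 1.0) * w) + params.root_width_delta * w

    crown = ~root
    t = np.clip((z[crown] - Lr) / Hc, 0.0, 1.0)  # 0 at CEJ, 1 incisal
    bulge = _smoothstep(t / params.crown_bulge)
    taper = 1.0 - params.crown_taper_md * _smoothstep((t - 0.55) / 0.45)
    a[crown] = (ca + (Aa - ca) * bulge) * taper
    # incisor crowns thin toward the incisal edge in the faciolingual axis
    b[crown] = (
        (cb + (Ab - cb) * bulge)
        * taper
        * (1.0 - params.crown_taper_fl * _smoothstep((t - 0.4) / 0.6))
    )
    p[crown] = 2.0 + 2.0 * _smoothstep(t / 0.6)
    return a, b, p


def _bend_offset(params: ToothParams, z: np.ndarray) -> np.ndarray:
    """Lateral centerline offset (per station, (n, 3)) from root dilaceration."""
    out = np.zeros((len(z), 3))
    if params.bend_angle == 0:
        return out
    z_bend = params.root_length * (1.0 - params.bend_onset)
    mag = np.tan(np.radians(params.bend_angle)) * np.maximum(z_bend - z, 0.0)
    direction = {
        "mesial": np.array([1.0, 0.0, 0.0]),
        "distal": np.array([-1.0, 0.0, 0.0]),
        "lingual": np.array([0.0, 1.0, 0.0]),
    }[params.bend_direction]
    return mag[:, None] * direction[None, :]


def _superellipse_radius(psi: np.ndarray, a, b, p) -> np.ndarray:
    c, s = np.cos(psi), np.sin(psi)
    return (np.abs(c / a) ** p + np.abs(s / b) ** p) ** (-1.0 / p)


def generate_tooth(params: ToothParams) -> TriangleMesh:
    """Build one watertight genus-0 incisor surface from its parameters."""
    params.validate()
    Lr, H = params.root_length, params.total_length
    ar = params.apex_radius
    cap_h = min(0.35 * params.crown_height, 2.0)  # incisal cap height

    # axial stations: apex cap (sphere profile), shaft, incisal cap
    z_apex = ar * (1.0 - np.cos(np.linspace(0.12, 0.5, 5) * np.pi))
    z_shaft = np.linspace(z_apex[-1], H - cap_h, 36)[1:]
    # cap stations ascend from the cap base toward (but not onto) the pole
    cap_ang = np.linspace(0.1, 0.5, 6)[:-1] * np.pi
    z_top = H - cap_h * (1.0 - np.sin(cap_ang))
    z = np.concatenate([z_apex, z_shaft, z_top])

    a, b, p = _profile(params, z)
    # spherical apex cap: shrink the section toward the apex point
    in_cap = z < ar
    cap_scale = np.sqrt(np.clip(1.0 - ((ar - z[in_cap]) / ar) ** 2, 0.0, 1.0))
    a[in_cap] = ar * cap_scale
    b[in_cap] = ar * cap_scale * (params.cervical_width_fl / params.cervical_width_md)
    # incisal cap: round off the crown end
    top_cap = z > H - cap_h
    top_scale = np.sqrt(np.clip(1.0 - ((z[top_cap] - (H - cap_h)) / cap_h) ** 2, 0.0, 1.0))
    a[top_cap] *= np.maximum(top_scale, 0.05)
    b[top_cap] *= np.maximum(top_scale, 0.05)

    offsets = _bend_offset(params, z)
    psi = np.linspace(0.0, 2.0 * np.pi, _N_THETA, endpoint=False)

    rings = []
    tau = np.radians(params.torsion_deg) * z / max(H, 1e-9)  # twist per station
    for zi, ai, bi, pi, off, tk in zip(z, a, b, p, offsets, tau):
        r = _superellipse_radius(psi, ai, bi, pi)
        x = r * np.cos(psi)
        y = r * np.sin(psi)
        ring = np.column_stack(
            [
                np.cos(tk) * x - np.sin(tk) * y + off[0],
                np.sin(tk) * x + np.cos(tk) * y + off[1],
                np.full(_N_THETA, zi),
            ]
        )
        rings.append(ring)
    verts = np.vstack(rings)
    apex_point = np.concatenate([_bend_offset(params, np.array([0.0]))[0][:2], [0.0]])
    top_point = np.array([0.0, 0.0, H])
    verts = np.vstack([verts, apex_point, top_point])
    i_apex, i_top = len(verts) - 2, len(verts) - 1

    faces = []
    n_rings = len(rings)
    for r0 in range(n_rings - 1):
        base0, base1 = r0 * _N_THETA, (r0 + 1) * _N_THETA
        for k in range(_N_THETA):
            k1 = (k + 1) % _N_THETA
            faces.append((base0 + k, base0 + k1, base1 + k))
            faces.append((base0 + k1, base1 + k1, base1 + k))
    for k in range(_N_THETA):  # apex fan (ring 0)
        k1 = (k + 1) % _N_THETA
        faces.append((i_apex, k1, k))
    base_top = (n_rings - 1) * _N_THETA
    for k in range(_N_THETA):  # incisal fan (last ring)
        k1 = (k + 1) % _N_THETA
        faces.append((i_top, base_top + k, base_top + k1))
    faces = np.array(faces, dtype=np.int64)

    mesh = TriangleMesh(verts, faces)
    tm = mesh.to_trimesh()
    if tm.volume < 0:
        mesh = TriangleMesh(verts, faces[:, ::-1])

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        eps = rng.normal(0.0, params.noise_sigma, size=len(verts))
        radial = verts.copy()
        centers = np.zeros_like(verts)
        centers[: n_rings * _N_THETA, :2] = np.repeat(offsets[:, :2], _N_THETA, axis=0)
        centers[:, 2] = verts[:, 2]
        d = verts - centers
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        d = np.where(nrm > 1e-9, d / np.maximum(nrm, 1e-9), 0.0)
        d[i_apex] = (0.0, 0.0, -1.0)
        d[i_top] = (0.0, 0.0, 1.0)
        mesh = TriangleMesh(mesh.vertices + d * eps[:, None], mesh.faces)
    return mesh


def _jitter_params(p: ToothParams, rng: np.random.Generator, scale: float) -> ToothParams:
    """Sample one subject's anatomy around the template parameters."""
    if scale == 0:
        return p
    sd = ANATOMICAL_SD
    q = replace(p)
    q.crown_width_md = max(4.0, p.crown_width_md + scale * rng.normal(0, sd["crown_width_md"]))
    q.crown_thickness_fl = max(3.0, p.crown_thickness_fl + scale * rng.normal(0, sd["crown_thickness_fl"]))
    q.crown_height = max(5.0, p.crown_height + scale * rng.normal(0, sd["crown_height"]))
    q.root_length = max(6.0, p.root_length + scale * rng.normal(0, sd["root_length"]))
    rel = 1.0 + scale * rng.normal(0, sd["cervical_rel"])
    q.cervical_width_md = p.cervical_width_md * max(rel, 0.5)
    q.cervical_width_fl = p.cervical_width_fl * max(rel, 0.5)
    q.apex_radius = p.apex_radius * max(0.3, 1.0 + scale * rng.normal(0, sd["apex_radius_rel"]))
    q.torsion_deg = p.torsion_deg + scale * rng.normal(0, sd["torsion_deg"])
    q.crown_taper_md = float(np.clip(p.crown_taper_md + scale * rng.normal(0, sd["crown_taper_md"]), 0.05, 0.5))
    q.crown_taper_fl = float(np.clip(p.crown_taper_fl + scale * rng.normal(0, sd["crown_taper_fl"]), 0.1, 0.7))
    q.crown_bulge = float(np.clip(p.crown_bulge + scale * rng.normal(0, sd["crown_bulge"]), 0.25, 0.65))
    return q


def generate_cohort(spec: CohortSpec) -> list[tuple[TriangleMesh, str, ToothParams]]:
    """Generate ``spec.n`` teeth of one subgroup.

    Each tooth gets its own anatomy (template plus inter-subject jitter)
    and an independent surface-noise seed, both derived from the cohort
    seed.
    """
    template = apply_subgroup_effect(spec.base_params, spec.subgroup)
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n)
    out = []
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        p = _jitter_params(template, rng, spec.anatomical_scale)
        p.seed = int(s % (2**31))
        mesh = generate_tooth(p)
        # individual surface relief: smooth correlated field, a proxy for
        # the high-dimensional shape variation of real crowns and roots
        # (lobes, ridges, wear facets) that parameter jitter cannot span
        field_sd = spec.anatomical_scale * ANATOMICAL_SD["surface_field"]
        if field_sd > 0:
            mesh = perturb_as_second_rater(
                mesh, field_sd, seed=int((s + 1) % (2**31)), smoothing_rounds=8
            )
        out.append((mesh, spec.subgroup, p))
    return out


def generate_study(
    sizes: dict[str, int], seed: int = 0, base_params: ToothParams | None = None
) -> list[tuple[TriangleMesh, str, ToothParams]]:
    """Concatenate cohorts for several subgroups (one study arm)."""
    base = base_params or ToothParams()
    child = np.random.SeedSequence(seed).spawn(len(sizes))
    out = []
    for (label, n), ss in zip(sizes.items(), child):
        if n == 0:
            continue
        out.extend(
            generate_cohort(
                CohortSpec(subgroup=label, n=n, seed=int(ss.generate_state(1)[0] % (2**31)), base_params=base)
            )
        )
    return out


def perturb_as_second_rater(
    mesh: TriangleMesh, sigma_mm: float, seed: int, smoothing_rounds: int = 3
) -> TriangleMesh:
    """Smooth, spatially correlated boundary displacement along vertex normals.

    Gaussian vertex noise is low-pass filtered over the mesh graph
    (neighbourhood averaging) and rescaled to standard deviation
    ``sigma_mm``, mimicking localized rater disagreement rather than white
    noise.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=mesh.n_vertices)
    # neighbourhood averaging over the vertex graph
    from scipy import sparse

    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    data = np.ones(len(rows))
    A = sparse.coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2)
    A = ((A + A.T) > 0).astype(np.float64).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    for _ in range(smoothing_rounds):
        eps = (A @ eps + eps) / (deg + 1.0)
    sd = eps.std()
    if sd > 0:
        eps *= sigma_mm / sd
    normals = vertex_normals(mesh)
    return TriangleMesh(
        mesh.vertices + normals * eps[:, None], mesh.faces.copy()
    )
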
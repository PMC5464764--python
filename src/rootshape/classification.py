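"""Root-morphology subgroup assignment from regional signed-distance summaries.

Each tooth is compared with the cohort average through its signed distance
map; regional summaries (apical length change, cervical width change,
mid/apical circumference change, apex deviation) feed a deterministic
decision tree mirroring the clinical subgroup definitions: neutral, blunt,
long, conical, short, and mesial / distal / lingual dilaceration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspondence import PointDistributionModel
from .morphometry import pdm_normals, signed_distance_map

__all__ = [
    "ToothFrame",
    "RegionalFeatures",
    "ClassificationThresholds",
    "SUBGROUP_LABELS",
    "define_tooth_frame",
    "regional_summaries",
    "classify_root",
    "classify_cohort",
]

SUBGROUP_LABELS = (
    "neutral",
    "blunt",
    "long",
    "conical",
    "short",
    "mesial_dilaceration",
    "distal_dilaceration",
    "lingual_dilaceration",
)

#: |normal . long_axis| below this counts as a laterally-facing point
_LATERAL_NORMAL_MAX = 0.7


@dataclass
class ToothFrame:
    """Anatomical frame of the reference tooth.

    ``long_axis`` points crown-to-apex; axial coordinates run from 0 at the
    incisal extreme to the full axial extent at the apex.  ``cej_fraction``
    is the fraction of the axial extent occupied by the crown (the
    cemento-enamel junction approximated as a fixed fraction of length).
    """

    origin: np.ndarray
    long_axis: np.ndarray
    mesiodistal: np.ndarray
    faciolingual: np.ndarray
    cej_fraction: float = 0.40

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        for name in ("long_axis", "mesiodistal", "faciolingual"):
            v = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            setattr(self, name, v / np.linalg.norm(v))
        G = np.stack([self.mesiodistal, self.faciolingual, self.long_axis])
        if not np.allclose(G @ G.T, np.eye(3), atol=1e-6):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(G) < 0:
            raise ValueError("frame must be right-handed")

    def axial(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.long_axis


@dataclass
class RegionalFeatures:
    """Per-tooth regional summaries (mm) driving subgroup assignment.

    delta_apex_len      signed apical length change along the long axis
    delta_cervical_width  width change over the cervical third of the root
                        (2x the mean signed distance: both surfaces move)
    delta_mid_circum    circumference change over the middle + apical thirds
                        (2*pi x the mean signed distance of lateral points)
    apex_deviation      apex-region centroid offset in frame coordinates
                        (mesiodistal, faciolingual, axial)
    apex_bluntness      mean signed distance over the apical cap
    """

    delta_apex_len: float
    delta_cervical_width: float
    delta_mid_circum: float
    apex_deviation: np.ndarray
    apex_bluntness: float

    def __post_init__(self) -> None:
        self.apex_deviation = np.asarray(self.apex_deviation, dtype=np.float64).reshape(3)
        values = [
            self.delta_apex_len, self.delta_cervical_width,
            self.delta_mid_circum, self.apex_bluntness,
            *self.apex_deviation,
        ]
        if not np.all(np.isfinite(values)):
            raise ValueError("regional features must be finite")

    @property
    def lateral_deviation(self) -> float:
        return float(np.hypot(self.apex_deviation[0], self.apex_deviation[1]))


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision-tree cutoffs (mm), sized so the observed inter-rater noise
    floor (~0.06 mm mean, <0.5 mm point maxima) cannot trigger a
    non-neutral call."""

    length: float = 1.0  # |delta_apex_len| beyond which length is abnormal
    width: float = 0.5  # |width / circumference change| cutoff
    deviation: float = 1.0  # lateral apex deviation for dilaceration


def define_tooth_frame(
    reference: PointDistributionModel,
    apex_hint,
    mesiodistal_hint=None,
    cej_fraction: float = 0.40,
    min_axis_ratio: float = 1.1,
) -> ToothFrame:
    """Principal-axes frame of the reference: long axis signed toward the apex."""
    pts = reference.points
    c = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[0] / max(s[1], 1e-12) < min_axis_ratio:
        raise ValueError("no dominant axis: shape too isotropic for a tooth frame")
    long_axis = vt[0]
    apex = np.asarray(apex_hint, dtype=np.float64)
    if float(long_axis @ apex) < 0:
        long_axis = -long_axis
    md = vt[1]
    if mesiodistal_hint is not None:
        if float(md @ np.asarray(mesiodistal_hint, dtype=np.float64)) < 0:
            md = -md
    fl = np.cross(long_axis, md)
    ax = c @ long_axis
    origin = pts[int(np.argmin(ax))]  # incisal extreme
    return ToothFrame(origin, long_axis, md, fl, cej_fraction)


def regional_summaries(
    sdm: np.ndarray,
    individual: PointDistributionModel,
    reference: PointDistributionModel,
    frame: ToothFrame,
    min_region_points: int = 20,
) -> RegionalFeatures:
    """Partition the root into thirds along the reference's axial coordinate
    and summarize the signed distances per region."""
    sdm = np.asarray(sdm, dtype=np.float64)
    if not (len(sdm) == individual.n_points == reference.n_points):
        raise ValueError("point count mismatch")
    ax_ref = frame.axial(reference.points)
    ax_ind = frame.axial(individual.points)
    extent = float(ax_ref.max() - ax_ref.min())
    t = (ax_ref - ax_ref.min()) / extent  # 0 incisal ... 1 apex
    root = t > frame.cej_fraction
    tr = (t - frame.cej_fraction) / (1.0 - frame.cej_fraction)
    cervical = root & (tr < 1.0 / 3.0)
    middle = root & (tr >= 1.0 / 3.0) & (tr < 2.0 / 3.0)
    apical = root & (tr >= 2.0 / 3.0)

    def _apical_cap(ax: np.ndarray, extent_fraction: float, floor: int) -> np.ndarray:
        """Points within the apical ``extent_fraction`` of a shape's own
        axial extent, widened to at least ``floor`` points."""
        lo, hi = float(ax.min()), float(ax.max())
        mask = ax >= hi - extent_fraction * (hi - lo)
        if mask.sum() < floor:
            cut = np.sort(ax)[-floor]
            mask = ax >= cut
        return mask

    # apical cap measured as a fraction of the *root* extent
    root_frac = 1.0 - frame.cej_fraction
    apex5_ref = _apical_cap(ax_ref, 0.05 * root_frac, min_region_points)
    normals = pdm_normals(reference)
    lateral = np.abs(normals @ frame.long_axis) < _LATERAL_NORMAL_MAX
    for name, mask in (
        ("cervical", cervical), ("middle", middle), ("apical", apical),
        ("apical cap", apex5_ref),
    ):
        if mask.sum() < min_region_points:
            raise ValueError(
                f"sampling too coarse: only {int(mask.sum())} points in the {name} region"
            )
    # apical length change: difference of (robust) axial extents
    delta_apex_len = float(
        np.quantile(ax_ind, 0.99) - np.quantile(ax_ref, 0.99)
    )

    # width/circumference changes compare the root *radius profile* of the
    # two shapes at matched relative levels of each root's own extent.
    # This is intrinsic (alignment-free) and decoupled from length
    # differences: on a tapered root, comparing widths at matched absolute
    # heights would read a pure length change as a width change.
    def _radius_profile(points: np.ndarray, ax: np.ndarray, edges: np.ndarray) -> np.ndarray:
        lo, hi = float(ax.min()), float(ax.max())
        tt = (ax - lo) / (hi - lo)
        rr = (tt - frame.cej_fraction) / (1.0 - frame.cej_fraction)
        radii = np.full(len(edges) - 1, np.nan)
        for k, (a0, a1) in enumerate(zip(edges[:-1], edges[1:])):
            m = (rr >= a0) & (rr < a1)
            if m.sum() < 8:
                continue
            slab = points[m]
            lat = slab - slab.mean(axis=0)
            lat = lat - np.outer(lat @ frame.long_axis, frame.long_axis)
            radii[k] = np.linalg.norm(lat, axis=1).mean()
        return radii

    cerv_edges = np.linspace(0.0, 1.0 / 3.0, 4)
    mid_edges = np.linspace(1.0 / 3.0, 0.9, 7)  # stop short of the apex cap
    r_ind_c = _radius_profile(individual.points, ax_ind, cerv_edges)
    r_ref_c = _radius_profile(reference.points, ax_ref, cerv_edges)
    r_ind_m = _radius_profile(individual.points, ax_ind, mid_edges)
    r_ref_m = _radius_profile(reference.points, ax_ref, mid_edges)
    with np.errstate(invalid="ignore"):
        delta_cervical_width = float(2.0 * np.nanmean(r_ind_c - r_ref_c))
        delta_mid_circum = float(2.0 * np.pi * np.nanmean(r_ind_m - r_ref_m))
    if not np.isfinite(delta_cervical_width) or not np.isfinite(delta_mid_circum):
        raise ValueError("sampling too coarse: empty radius-profile slabs")
    # apex deviation: lateral offset of the apical cap from the extrapolated
    # axis of the shape's *own* upper root (how dilaceration is defined
    # clinically), computed per shape and differenced against the
    # reference.  Being intrinsic to each shape, the measure is invariant
    # to residual rigid-pose differences from the cohort alignment.
    def _own_apex_offset(points: np.ndarray, ax: np.ndarray) -> np.ndarray:
        lo, hi = float(ax.min()), float(ax.max())
        tt = (ax - lo) / (hi - lo)
        rr = (tt - frame.cej_fraction) / (1.0 - frame.cej_fraction)
        # straight-root axis from the upper half of the root (clear of any
        # apical bend), as the line through the two quarter centroids
        c_up = points[(rr >= 0.0) & (rr < 0.25)].mean(axis=0)
        c_mid = points[(rr >= 0.25) & (rr < 0.5)].mean(axis=0)
        axis = c_mid - c_up
        axis = axis / np.linalg.norm(axis)
        # centerline of the apical third from slab centroids, extrapolated
        # to the apex level: estimates the deviation *at the apex* without
        # the low bias of averaging over a cap
        edges = np.linspace(2.0 / 3.0, 1.0, 5)
        slabs = []
        for a0, a1 in zip(edges[:-1], edges[1:]):
            m = (rr >= a0) & (rr <= a1)
            if m.sum() >= 5:
                slabs.append((ax[m].mean(), points[m].mean(axis=0)))
        apex_level = hi
        if len(slabs) >= 2:
            zs = np.array([s[0] for s in slabs])
            cs = np.stack([s[1] for s in slabs])
            A = np.column_stack([np.ones_like(zs), zs - zs.mean()])
            coef, *_ = np.linalg.lstsq(A, cs, rcond=None)
            apex_c = coef[0] + coef[1] * (apex_level - zs.mean())
        else:  # degenerate sampling: fall back to the apical cap centroid
            cut = np.sort(ax)[-10]
            apex_c = points[ax >= cut].mean(axis=0)
        lever = (apex_c - c_mid) @ axis
        return apex_c - (c_mid + lever * axis)

    dev = _own_apex_offset(individual.points, ax_ind) - _own_apex_offset(
        reference.points, ax_ref
    )
    apex_deviation = np.array(
        [dev @ frame.mesiodistal, dev @ frame.faciolingual, dev @ frame.long_axis]
    )
    apex_bluntness = float(sdm[apex5_ref].mean())
    return RegionalFeatures(
        delta_apex_len=delta_apex_len,
        delta_cervical_width=delta_cervical_width,
        delta_mid_circum=delta_mid_circum,
        apex_deviation=apex_deviation,
        apex_bluntness=apex_bluntness,
    )


def classify_root(
    features: RegionalFeatures,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> str:
    """Deterministic decision tree over the regional features (first match wins).

    1. lateral apex deviation beyond the cutoff -> dilaceration, direction
       from the dominant lateral component (facial deviations are folded
       onto the lingual axis and reported as lingual);
    2. longer apex and larger circumference -> long;
    3. shorter apex and smaller circumference -> short;
    4. shorter apex and wider cervix -> blunt;
    5. smaller circumference alone -> conical;
    6. otherwise neutral.
    """
    th = thresholds
    if th.length <= 0 or th.width <= 0 or th.deviation <= 0:
        raise ValueError("thresholds must be positive")
    if features.lateral_deviation > th.deviation:
        md, fl = features.apex_deviation[0], features.apex_deviation[1]
        if abs(md) >= abs(fl):
            return "mesial_dilaceration" if md > 0 else "distal_dilaceration"
        return "lingual_dilaceration"
    if features.delta_apex_len > th.length and features.delta_mid_circum > th.width:
        return "long"
    if features.delta_apex_len < -th.length and features.delta_mid_circum < -th.width:
        return "short"
    if features.delta_apex_len < -th.length and features.delta_cervical_width > th.width:
        return "blunt"
    if features.delta_mid_circum < -th.width:
        return "conical"
    return "neutral"


def classify_cohort(
    aligned_pdms: list[PointDistributionModel],
    reference: PointDistributionModel,
    frame: ToothFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
):
    """Classify every tooth of an aligned cohort against the reference mean.

    Returns a list of (tooth_id, label, RegionalFeatures).
    """
    normals = pdm_normals(reference)
    out = []
    for pdm in aligned_pdms:
        sdm = signed_distance_map(pdm, reference, normals)
        feats = regional_summaries(sdm, pdm, reference, frame)
        out.append((pdm.tooth_id, classify_root(feats, thresholds), feats))
    return out
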
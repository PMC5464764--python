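"""Inter-rater reproducibility of surface models.

Repeated segmentations of the same tooth are compared through per-vertex
closest-point surface distances (exact point-to-triangle, signed by the
second surface's outward normal) and through intraclass correlation of the
scalar surface summaries (point/triangle counts, area, volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import SurfaceDistanceQuery
from .geometry_io import TriangleMesh, mesh_properties

__all__ = [
    "PairDistanceSummary",
    "ValidationReport",
    "closest_point_distances",
    "icc_absolute_agreement",
    "validation_report",
    "aggregate_summaries",
]


@dataclass
class PairDistanceSummary:
    """Distance statistics of one repeated-segmentation pair (mm).

    ``median``/``mean``/``sd`` summarize the signed distances; ``max`` is
    the largest absolute difference.  Absolute-value summaries are carried
    alongside so either reading of a signed-distance table is recoverable.
    """

    case_id: str = ""
    tooth: str = "UR1"
    voxel_mm: float = np.nan
    median: float = np.nan
    max: float = np.nan
    mean: float = np.nan
    sd: float = np.nan
    abs_median: float = np.nan
    abs_mean: float = np.nan
    abs_sd: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.median) and np.isfinite(self.max):
            if abs(self.median) > abs(self.max) + 1e-12:
                raise ValueError("median cannot exceed the maximum difference")
        if np.isfinite(self.sd) and self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class ValidationReport:
    """Per-pair rows plus the aggregate statistics and summary-scalar ICCs."""

    summaries: list = field(default_factory=list)
    average_mean: float = np.nan
    average_sd: float = np.nan
    max_range: tuple = (np.nan, np.nan)
    icc: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "case": s.case_id, "tooth": s.tooth, "voxel_mm": s.voxel_mm,
                "median": s.median, "max": s.max, "mean": s.mean, "sd": s.sd,
                "abs_median": s.abs_median, "abs_mean": s.abs_mean, "abs_sd": s.abs_sd,
            }
            for s in self.summaries
        ]
        df = pd.DataFrame(rows)
        total = {
            "case": "total", "tooth": "", "voxel_mm": np.nan,
            "median": np.nan, "max": np.nan,
            "mean": self.average_mean, "sd": self.average_sd,
            "abs_median": np.nan, "abs_mean": np.nan, "abs_sd": np.nan,
        }
        return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def closest_point_distances(
    meshA: TriangleMesh,
    meshB: TriangleMesh,
    case_id: str = "",
    tooth: str = "UR1",
    voxel_mm: float = np.nan,
):
    """Signed closest-point distances from every vertex of A to surface B.

    Distances are exact point-to-triangle (never point-to-vertex), signed
    positive where A lies outside B.  Returns (per-vertex signed distances,
    PairDistanceSummary).
    """
    if meshA.n_vertices == 0 or meshB.n_vertices == 0 or meshB.n_faces == 0:
        raise ValueError("cannot compare empty meshes")
    query = SurfaceDistanceQuery(meshB.vertices, meshB.faces)
    signed, _, _ = query.signed_query(meshA.vertices)
    summary = PairDistanceSummary(
        case_id=case_id,
        tooth=tooth,
        voxel_mm=voxel_mm,
        median=float(np.median(signed)),
        max=float(np.max(np.abs(signed))),
        mean=float(np.mean(signed)),
        sd=float(np.std(signed, ddof=1)) if len(signed) > 1 else 0.0,
        abs_median=float(np.median(np.abs(signed))),
        abs_mean=float(np.mean(np.abs(signed))),
        abs_sd=float(np.std(np.abs(signed), ddof=1)) if len(signed) > 1 else 0.0,
    )
    return signed, summary


def icc_absolute_agreement(rater1, rater2, variant: str = "ICC2") -> float:
    """Intraclass correlation of two raters' paired measurements.

    Default is ICC(2,1): two-way random effects, absolute agreement,
    single measurement, from the two-way ANOVA decomposition.  ICC(3,1)
    (consistency) is selectable with ``variant='ICC3'``.
    """
    x = np.asarray(rater1, dtype=np.float64)
    y = np.asarray(rater2, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("raters must be equal-length 1D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr < 1e-300 and mse < 1e-300 and msc < 1e-300:
        raise ValueError("ICC undefined: no variance in subjects or raters")
    if variant == "ICC2":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif variant == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("variant must be 'ICC2' or 'ICC3'")
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def aggregate_summaries(summaries) -> dict:
    """Totals row of a repeated-segmentation table: average of the per-pair
    means, average of the per-pair SDs, and the range of the maxima."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    maxima = np.array([s.max for s in summaries])
    return {
        "average_mean": float(means.mean()),
        "average_sd": float(sds.mean()),
        "max_range": (float(maxima.min()), float(maxima.max())),
    }


def validation_report(pairs, icc_variant: str = "ICC2") -> ValidationReport:
    """Full reproducibility report over (meshA, meshB[, metadata]) pairs.

    Metadata may carry ``case_id``, ``tooth``, ``voxel_mm``.  ICCs of the
    four surface summary scalars are computed across pairs when at least 3
    pairs are given.
    """
    summaries = []
    scalars = {"n_points": [], "n_triangles": [], "surface_area": [], "volume": []}
    for pair in pairs:
        meshA, meshB = pair[0], pair[1]
        meta = pair[2] if len(pair) > 2 else {}
        _, summ = closest_point_distances(
            meshA, meshB,
            case_id=str(meta.get("case_id", len(summaries) + 1)),
            tooth=meta.get("tooth", "UR1"),
            voxel_mm=meta.get("voxel_mm", np.nan),
        )
        summaries.append(summ)
        pa, pb = mesh_properties(meshA), mesh_properties(meshB)
        scalars["n_points"].append((pa.n_points, pb.n_points))
        scalars["n_triangles"].append((pa.n_triangles, pb.n_triangles))
        scalars["surface_area"].append((pa.surface_area, pb.surface_area))
        scalars["volume"].append(
            (pa.enclosed_volume or np.nan, pb.enclosed_volume or np.nan)
        )
    agg = aggregate_summaries(summaries)
    icc = {}
    if len(summaries) >= 3:
        for name, vals in scalars.items():
            arr = np.array(vals, dtype=np.float64)
            if np.isfinite(arr).all():
                try:
                    icc[name] = icc_absolute_agreement(
                        arr[:, 0], arr[:, 1], variant=icc_variant
                    )
                except ValueError:
                    icc[name] = np.nan
    return ValidationReport(
        summaries=summaries,
        average_mean=agg["average_mean"],
        average_sd=agg["average_sd"],
        max_range=agg["max_range"],
        icc=icc,
    )
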
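"""Orthogonal thickness morphometry of capillary ultrastructure.

The thickness of a basement membrane or intercellular cleft is measured
from a pair of traced boundaries (inner and outer polylines, in nm): at a
sample point on the inner trace, the local tangent is estimated by central
difference and the thickness is the distance along the local normal to the
first crossing of the outer trace.  Measurements beyond a sanity bound
(1 μm — far thicker than either structure) or whose normal ray misses the
outer trace are skipped.

Per-capillary minimum-sampling rules (≥4 basement-membrane, ≥2 cleft
measurements) gate which capillaries enter summaries; group summaries pool
technical replicates by default, with per-capillary means available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

__all__ = [
    "BoundaryTracePair",
    "ThicknessMeasurement",
    "orthogonal_thickness",
    "measure_pair",
    "enforce_sampling",
    "group_summary",
    "percent_change",
    "STRUCTURES",
    "MIN_MEASUREMENTS",
    "THICKNESS_SANITY_BOUND_NM",
]

logger = logging.getLogger(__name__)

STRUCTURES = ("basement_membrane", "intercellular_cleft")
#: Minimum measurements per capillary for a structure to enter summaries.
MIN_MEASUREMENTS = {"basement_membrane": 4, "intercellular_cleft": 2}
#: Default number of equidistant sample points along the inner trace.
DEFAULT_SAMPLES = {"basement_membrane": 8, "intercellular_cleft": 4}
#: Upper sanity bound on a single thickness (nm).
THICKNESS_SANITY_BOUND_NM = 1000.0


@dataclass(frozen=True)
class BoundaryTracePair:
    """Inner and outer boundary traces of one structure on one capillary."""

    inner: np.ndarray  # (n, 2) nm coordinates, ordered along the boundary
    outer: np.ndarray
    structure: str
    capillary_id: str = ""
    segment: str = ""
    region: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        for name in ("inner", "outer"):
            pts = np.asarray(getattr(self, name), dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise ValueError(f"{name} trace must be an (n >= 3, 2) point array")
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"{name} trace contains non-finite coordinates")
            object.__setattr__(self, name, pts)
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; valid: {STRUCTURES}")
        if LineString(self.inner).crosses(LineString(self.outer)):
            raise ValueError("inner and outer traces must not intersect")


@dataclass(frozen=True)
class ThicknessMeasurement:
    """One orthogonal thickness (nm) with its sample provenance."""

    thickness_nm: float
    structure: str
    capillary_id: str
    segment: str
    region: str
    group: str
    sample_index: int

    def __post_init__(self) -> None:
        if not 0 < self.thickness_nm < THICKNESS_SANITY_BOUND_NM:
            raise ValueError(
                f"thickness_nm must lie in (0, {THICKNESS_SANITY_BOUND_NM}), "
                f"got {self.thickness_nm}"
            )


def _tangent_at(inner: LineString, s: float, delta: float) -> np.ndarray | None:
    """Central-difference tangent at arc-length s (one-sided at endpoints)."""
    length = inner.length
    lo, hi = max(s - delta, 0.0), min(s + delta, length)
    p_lo = np.asarray(inner.interpolate(lo).coords[0])
    p_hi = np.asarray(inner.interpolate(hi).coords[0])
    t = p_hi - p_lo
    norm = float(np.hypot(*t))
    if norm < 1e-12:
        return None
    return t / norm


def orthogonal_thickness(
    pair: BoundaryTracePair,
    sample_point_nm: tuple[float, float] | np.ndarray,
    max_nm: float = THICKNESS_SANITY_BOUND_NM,
) -> float | None:
    """Thickness at one sample point: normal-ray distance to the outer trace.

    The sample point must lie on (or within numerical tolerance of) the
    inner trace.  The normal is cast in both directions; the nearest
    crossing of the outer trace within *max_nm* is returned, or ``None``
    (skip) when the ray misses the outer trace or the tangent is degenerate.
    """
    inner_ls = LineString(pair.inner)
    outer_ls = LineString(pair.outer)
    p = Point(float(sample_point_nm[0]), float(sample_point_nm[1]))
    s = inner_ls.project(p)
    delta = max(inner_ls.length * 1e-3, 1e-6)
    tangent = _tangent_at(inner_ls, s, delta)
    if tangent is None:
        logger.warning("degenerate tangent at %s on capillary %s; skipping",
                       sample_point_nm, pair.capillary_id)
        return None
    normal = np.array([-tangent[1], tangent[0]])
    base = np.asarray([p.x, p.y])
    ray = LineString([base - max_nm * normal, base + max_nm * normal])
    hit = ray.intersection(outer_ls)
    if hit.is_empty:
        return None
    if hit.geom_type == "Point":
        candidates = [hit]
    else:
        candidates = [g for g in getattr(hit, "geoms", []) if g.geom_type == "Point"]
        if not candidates:
            return None
    d = min(math.hypot(g.x - base[0], g.y - base[1]) for g in candidates)
    if not 0 < d < max_nm:
        return None
    return float(d)


def measure_pair(
    pair: BoundaryTracePair,
    n_samples: int | None = None,
    max_nm: float = THICKNESS_SANITY_BOUND_NM,
) -> list[ThicknessMeasurement]:
    """Measure thickness at equidistant sample points along the inner trace.

    Defaults to 8 sample points for basement membranes and 4 for clefts.
    Sample points whose normal ray misses the outer trace are skipped.
    """
    if n_samples is None:
        n_samples = DEFAULT_SAMPLES[pair.structure]
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    inner_ls = LineString(pair.inner)
    closed = bool(np.allclose(pair.inner[0], pair.inner[-1]))
    if closed:
        fractions = np.arange(n_samples) / n_samples
    else:
        fractions = np.linspace(0.0, 1.0, n_samples)
    out = []
    for k, f in enumerate(fractions):
        pt = inner_ls.interpolate(float(f) * inner_ls.length)
        t = orthogonal_thickness(pair, (pt.x, pt.y), max_nm=max_nm)
        if t is None:
            continue
        out.append(
            ThicknessMeasurement(
                thickness_nm=t,
                structure=pair.structure,
                capillary_id=pair.capillary_id,
                segment=pair.segment,
                region=pair.region,
                group=pair.group,
                sample_index=k,
            )
        )
    return out


_MEAS_COLUMNS = [
    "thickness_nm", "structure", "capillary_id", "segment", "region", "group",
    "sample_index",
]


def measurements_frame(measurements: list[ThicknessMeasurement]) -> pd.DataFrame:
    """Tidy DataFrame of thickness measurements."""
    if not measurements:
        return pd.DataFrame(columns=_MEAS_COLUMNS)
    return pd.DataFrame([m.__dict__ for m in measurements])[_MEAS_COLUMNS]


def enforce_sampling(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-capillary minimum-measurement rule.

    Returns ``(valid_measurements, capillary_means)``: capillaries with
    fewer than 4 basement-membrane or 2 cleft measurements are dropped from
    that structure's records; survivors are also reduced to per-capillary
    mean thicknesses.
    """
    if isinstance(measurements, list):
        measurements = measurements_frame(measurements)
    if measurements.empty:
        empty = measurements.iloc[0:0]
        return empty, pd.DataFrame(
            columns=["structure", "capillary_id", "segment", "region", "group",
                     "mean_nm", "n_measurements"]
        )
    counts = measurements.groupby(["structure", "capillary_id"])["thickness_nm"].transform("size")
    minimum = measurements["structure"].map(MIN_MEASUREMENTS)
    valid = measurements[counts >= minimum].reset_index(drop=True)
    caps = (
        valid.groupby(["structure", "capillary_id", "segment", "region", "group"],
                      as_index=False)
        .agg(mean_nm=("thickness_nm", "mean"), n_measurements=("thickness_nm", "size"))
    )
    return valid, caps


def group_summary(
    measurements: pd.DataFrame,
    level: str = "measurement",
    by: tuple[str, ...] = ("group", "segment", "region", "structure"),
) -> pd.DataFrame:
    """Mean ± SD per group × location × structure.

    ``level="measurement"`` pools technical replicates (individual
    measurements, matching how the study reports them); ``level="capillary"``
    first reduces to per-capillary means.  A cell with a single value gets
    SD 0 by convention.  Empty cells are simply absent.
    """
    valid, caps = enforce_sampling(measurements)
    if level == "measurement":
        data, value = valid, "thickness_nm"
    elif level == "capillary":
        data, value = caps, "mean_nm"
    else:
        raise ValueError(f"level must be 'measurement' or 'capillary', got {level!r}")
    if data.empty:
        return pd.DataFrame(columns=[*by, "mean_nm", "sd_nm", "n"])
    out = (
        data.groupby(list(by), as_index=False)
        .agg(mean_nm=(value, "mean"), sd_nm=(value, lambda v: v.std(ddof=1)), n=(value, "size"))
    )
    out["sd_nm"] = out["sd_nm"].fillna(0.0)
    return out


def percent_change(sham_mean_nm: float, injured_mean_nm: float) -> float:
    """Percent change of the injured mean relative to sham, one decimal place."""
    if not sham_mean_nm > 0:
        raise ValueError(f"sham mean must be > 0, got {sham_mean_nm}")
    return round(100.0 * (injured_mean_nm - sham_mean_nm) / sham_mean_nm, 1)
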
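"""Grid-based stereological counting and morphometric estimates.

A square point/line test system of pitch ``d`` is overlaid on a field at a
uniformly random offset.  Three raw tallies are taken per field:

* ``P``  — lattice points (line crossings) falling on vessel foreground,
* ``hI`` / ``vI`` — intersections of vessel profile boundaries with the
  horizontal and vertical line families,
* ``N``  — vessel profiles counted with an unbiased counting frame.

From these the classical design-based estimators follow: profile area
``A = d²·P`` (area-per-point rule), boundary length ``B = (π/2)·L·d`` with
``L = (hI + vI)/2`` (Cauchy–Crofton with total test-line length ``2·A/d``),
and, after normalisation by the region-of-interest area, numerical density
``N_A``, boundary density ``B_A``, areal density ``A_A`` and the
surface-to-volume ratio ``S/V = B_A / A_A``.

All physical coordinates are in micrometres; pixel (row, col) indices map to
physical coordinates as ``index · pixel_size_um`` with the origin at the
top-left corner and half-open pixel extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "Grid",
    "FieldCounts",
    "FieldEstimates",
    "CountingFrame",
    "generate_grid",
    "count_points",
    "count_intersections",
    "count_profiles",
    "boundary_length",
    "point_count_area",
    "apply_cavity_rule",
    "normalize_field",
    "quantify_field",
]

#: Default grid pitch (μm); d² = 150.0625 μm² ≈ the nominal 150 μm² per point.
DEFAULT_PITCH_UM = 12.25
#: Default field dimensions (μm) of one analysed image.
DEFAULT_FIELD_UM = (318.0, 429.0)
#: Default rendering / analysis resolution (μm per pixel).
DEFAULT_PIXEL_SIZE_UM = 0.33
#: Default cavity-fraction threshold above which a field is flagged missing.
DEFAULT_CAVITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the square test system overlaid on one field.

    Parameters
    ----------
    pitch_um
        Line spacing ``d``; the area associated with one lattice point is
        ``d²`` (150.0625 μm² at the default 12.25 μm).
    offset_x_um, offset_y_um
        Grid offsets in ``[0, pitch)``.  ``None`` means "draw uniformly at
        random" when the grid is generated with a seed.
    field_width_um, field_height_um
        Physical extent of the field.
    pixel_size_um
        Raster resolution used to sample masks at grid coordinates.
    """

    pitch_um: float = DEFAULT_PITCH_UM
    field_width_um: float = DEFAULT_FIELD_UM[0]
    field_height_um: float = DEFAULT_FIELD_UM[1]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    offset_x_um: float | None = None
    offset_y_um: float | None = None

    def __post_init__(self) -> None:
        if not self.pitch_um > 0:
            raise ValueError(f"pitch_um must be > 0, got {self.pitch_um}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        for name in ("field_width_um", "field_height_um"):
            dim = getattr(self, name)
            if not dim > self.pitch_um:
                raise ValueError(
                    f"{name} = {dim} must exceed the grid pitch "
                    f"({self.pitch_um} um) so at least one line falls inside"
                )
        for name in ("offset_x_um", "offset_y_um"):
            off = getattr(self, name)
            if off is not None and not (0 <= off < self.pitch_um):
                raise ValueError(f"{name} must lie in [0, pitch), got {off}")

    @property
    def area_per_point_um2(self) -> float:
        return self.pitch_um**2

    @property
    def field_area_um2(self) -> float:
        return self.field_width_um * self.field_height_um


@dataclass(frozen=True)
class Grid:
    """A realised test system: line coordinates and their crossings."""

    xs: np.ndarray  # x positions of vertical lines (μm)
    ys: np.ndarray  # y positions of horizontal lines (μm)
    pitch_um: float
    offset_x_um: float
    offset_y_um: float
    seed: int | None = None

    @property
    def n_points(self) -> int:
        return len(self.xs) * len(self.ys)

    def lattice(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) meshgrid of lattice-point coordinates (μm)."""
        return np.meshgrid(self.xs, self.ys)


def _line_positions(offset: float, pitch: float, extent: float) -> np.ndarray:
    """Positions offset + k·d strictly inside (0, extent)."""
    pos = np.arange(offset, extent, pitch)
    return pos[pos > 0]


def generate_grid(spec: GridSpec, seed: int | None = None) -> Grid:
    """Overlay a randomly offset square grid on the field.

    Offsets fixed in *spec* are honoured; otherwise they are drawn uniformly
    on ``[0, pitch)`` from ``numpy.random.default_rng(seed)``, so a fixed
    seed reproduces the grid exactly.  Lines lie strictly inside the field;
    depending on the offset each family has ``floor(dim/d)`` or one more
    line, with expectation ``dim/d`` under a uniform offset.
    """
    ox, oy = spec.offset_x_um, spec.offset_y_um
    if ox is None or oy is None:
        if seed is None:
            raise ValueError("seed required when grid offsets are not fixed in the spec")
        rng = np.random.default_rng(seed)
        draw_x, draw_y = rng.uniform(0.0, spec.pitch_um, size=2)
        ox = draw_x if ox is None else ox
        oy = draw_y if oy is None else oy
    xs = _line_positions(ox, spec.pitch_um, spec.field_width_um)
    ys = _line_positions(oy, spec.pitch_um, spec.field_height_um)
    if len(xs) == 0:
        raise ValueError("no vertical grid line fits: field_width_um smaller than one pitch")
    if len(ys) == 0:
        raise ValueError("no horizontal grid line fits: field_height_um smaller than one pitch")
    return Grid(xs=xs, ys=ys, pitch_um=spec.pitch_um, offset_x_um=ox, offset_y_um=oy, seed=seed)


def _check_masks(*masks: np.ndarray) -> None:
    shapes = {m.shape for m in masks if m is not None}
    if len(shapes) > 1:
        raise ValueError(f"mask dimensions differ: {sorted(shapes)}")


def _pixel_indices(coords: np.ndarray, pixel_size_um: float, n: int) -> np.ndarray:
    idx = np.floor(coords / pixel_size_um).astype(int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("grid extends beyond the raster field")
    return idx


def count_points(
    vessel_mask: np.ndarray,
    roi_mask: np.ndarray,
    grid: Grid,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[int, int]:
    """Count lattice points on vessel foreground inside the ROI.

    Returns ``(P, P_roi)`` where ``P_roi`` is the number of lattice points
    inside the ROI (an area cross-check: ``P_roi·d²`` estimates ROI area).
    """
    _check_masks(vessel_mask, roi_mask)
    h, w = vessel_mask.shape
    ix = _pixel_indices(grid.xs, pixel_size_um, w)
    iy = _pixel_indices(grid.ys, pixel_size_um, h)
    roi_hits = roi_mask[np.ix_(iy, ix)].astype(bool)
    vessel_hits = vessel_mask[np.ix_(iy, ix)].astype(bool) & roi_hits
    return int(vessel_hits.sum()), int(roi_hits.sum())


def count_intersections(
    vessel_mask: np.ndarray,
    roi_mask: np.ndarray,
    grid: Grid,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[int, int]:
    """Count boundary crossings of vessel profiles with the grid lines.

    Along each line the vessel mask (restricted to the ROI) is scanned at
    pixel resolution and foreground/background transitions are counted: an
    interior run of foreground contributes 2 (entry + exit), a run clipped
    by the field edge contributes 1.
    """
    _check_masks(vessel_mask, roi_mask)
    fg = vessel_mask.astype(bool) & roi_mask.astype(bool)
    h, w = fg.shape
    ix = _pixel_indices(grid.xs, pixel_size_um, w)
    iy = _pixel_indices(grid.ys, pixel_size_um, h)
    h_i = int(np.count_nonzero(np.diff(fg[iy, :], axis=1)))
    v_i = int(np.count_nonzero(np.diff(fg[:, ix], axis=0)))
    return h_i, v_i


@dataclass(frozen=True)
class CountingFrame:
    """Rectangular unbiased counting frame (μm, image coordinates).

    The right and top edges are inclusion edges; the left and bottom edges
    are forbidden (Gundersen rule).  The forbidden line is extended beyond
    the frame: upward from the top-left corner along the left edge, and
    rightward from the bottom-right corner along the bottom edge, so every
    profile in a tiling of frames is counted exactly once.
    """

    x0_um: float
    y0_um: float  # top edge (smaller y; origin is top-left)
    x1_um: float
    y1_um: float  # bottom edge (larger y) — forbidden

    def __post_init__(self) -> None:
        if not (self.x1_um > self.x0_um and self.y1_um > self.y0_um):
            raise ValueError("counting frame must have positive extent")


def count_profiles(
    labelled_mask: np.ndarray,
    frame: CountingFrame,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> int:
    """Count distinct labelled profiles by the unbiased counting-frame rule.

    A profile is counted if any of its pixels lies inside the frame and none
    touches the forbidden (left/bottom) line or its extensions.  Each label
    is counted at most once.
    """
    lab = np.asarray(labelled_mask)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("labelled mask must have an integer dtype of profile IDs")
    if lab.ndim != 2:
        raise ValueError("labelled mask must be 2-D")
    h, w = lab.shape
    px = pixel_size_um
    jx0 = max(int(math.floor(frame.x0_um / px)), 0)
    jx1 = min(int(math.ceil(frame.x1_um / px)), w)
    jy0 = max(int(math.floor(frame.y0_um / px)), 0)
    jy1 = min(int(math.ceil(frame.y1_um / px)), h)
    inside = np.unique(lab[jy0:jy1, jx0:jx1])
    inside = inside[inside > 0]
    # Forbidden line: left edge column from the image top down to the frame
    # bottom, plus bottom edge row from the frame left to the image right.
    left_col = lab[:jy1, jx0]
    bottom_row = lab[min(jy1, h) - 1, jx0:] if jy1 <= h else lab[h - 1, jx0:]
    forbidden = np.union1d(np.unique(left_col), np.unique(bottom_row))
    counted = np.setdiff1d(inside, forbidden, assume_unique=False)
    return int(counted.size)


def boundary_length(h_i: int, v_i: int, pitch_um: float = DEFAULT_PITCH_UM) -> float:
    """Raw boundary length ``B = (π/2)·L·d`` with ``L = (hI + vI)/2`` (μm).

    Dividing by the reference area gives the classical Cauchy–Crofton
    boundary density ``B_A = (π/2)·I_L`` for a square grid whose total
    test-line length is ``2·A/d``.
    """
    if h_i < 0 or v_i < 0:
        raise ValueError(f"intersection counts must be >= 0, got ({h_i}, {v_i})")
    if not pitch_um > 0:
        raise ValueError("pitch_um must be > 0")
    mean_intersections = 0.5 * (h_i + v_i)
    return 0.5 * math.pi * mean_intersections * pitch_um


def point_count_area(p: int, pitch_um: float = DEFAULT_PITCH_UM) -> float:
    """Raw profile area ``A = d²·P`` (μm²); each point stands for d² of area."""
    if p < 0:
        raise ValueError(f"point count must be >= 0, got {p}")
    return pitch_um**2 * p


def apply_cavity_rule(
    roi_mask: np.ndarray,
    cavity_mask: np.ndarray | None,
    threshold: float = DEFAULT_CAVITY_THRESHOLD,
) -> tuple[np.ndarray, float, bool]:
    """Exclude lesion-cavity area from the reference space.

    Returns ``(effective_roi, cavity_fraction, missing)``.  The effective
    ROI is ``roi AND NOT cavity``; when the cavity fraction reaches
    *threshold* the field is flagged missing and contributes no estimates
    (absent values, never zeros).  An empty ROI counts as fully cavitated.
    """
    roi = np.asarray(roi_mask).astype(bool)
    roi_px = int(roi.sum())
    if cavity_mask is None:
        cavity_px = 0
        effective = roi
    else:
        _check_masks(roi, cavity_mask)
        cav = np.asarray(cavity_mask).astype(bool)
        cavity_px = int((roi & cav).sum())
        effective = roi & ~cav
    fraction = 1.0 if roi_px == 0 else cavity_px / roi_px
    return effective, fraction, fraction >= threshold


@dataclass(frozen=True)
class FieldCounts:
    """Raw stereological tallies for one field."""

    points_on_vessel: int  # P
    intersections_h: int  # hI
    intersections_v: int  # vI
    profile_count: int  # N
    roi_area_mm2: float
    cavity_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("points_on_vessel", "intersections_h", "intersections_v", "profile_count"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.roi_area_mm2 < 0:
            raise ValueError("roi_area_mm2 must be >= 0")
        if not 0 <= self.cavity_fraction <= 1:
            raise ValueError("cavity_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FieldEstimates:
    """Normalised per-field read-outs; NaN throughout when missing."""

    vessel_density_per_mm2: float
    surface_density_um_per_mm2: float
    areal_density_um2_per_mm2: float
    surface_to_volume_per_um: float
    missing: bool = False

    @classmethod
    def absent(cls) -> "FieldEstimates":
        nan = float("nan")
        return cls(nan, nan, nan, nan, missing=True)


def normalize_field(
    counts: FieldCounts,
    pitch_um: float = DEFAULT_PITCH_UM,
    cavity_threshold: float = DEFAULT_CAVITY_THRESHOLD,
) -> FieldEstimates:
    """Normalise raw tallies to the ROI area of the field.

    Densities: ``N_A = N / area``, ``B_A = B / area`` (μm mm⁻²),
    ``A_A = A / area`` (μm² mm⁻²), ``S/V = B_A / A_A`` (μm⁻¹; NaN when no
    vessel area was sampled).  Fields whose cavity fraction reaches the
    threshold yield absent estimates.
    """
    if counts.cavity_fraction >= cavity_threshold:
        return FieldEstimates.absent()
    if counts.roi_area_mm2 <= 0:
        raise ValueError(
            "roi_area_mm2 is zero but the field is not flagged as cavity: "
            "this indicates a segmentation failure, not a cavity"
        )
    area = counts.roi_area_mm2
    n_a = counts.profile_count / area
    b_a = boundary_length(counts.intersections_h, counts.intersections_v, pitch_um) / area
    a_a = point_count_area(counts.points_on_vessel, pitch_um) / area
    sv = b_a / a_a if a_a > 0 else float("nan")
    return FieldEstimates(n_a, b_a, a_a, sv, missing=False)


def quantify_field(
    vessel_mask: np.ndarray,
    labelled_mask: np.ndarray,
    roi_mask: np.ndarray,
    cavity_mask: np.ndarray | None,
    spec: GridSpec,
    seed: int | None = None,
    cavity_threshold: float = DEFAULT_CAVITY_THRESHOLD,
) -> tuple[Grid, FieldCounts, FieldEstimates]:
    """Run the full per-field stereology: grid, raw counts, estimates.

    The counting frame for profile counting is the whole field with
    forbidden left/bottom edges.  Deterministic for a fixed
    (masks, spec, seed) triple.
    """
    _check_masks(vessel_mask, labelled_mask, roi_mask, cavity_mask)
    effective_roi, cavity_fraction, missing = apply_cavity_rule(
        roi_mask, cavity_mask, cavity_threshold
    )
    grid = generate_grid(spec, seed)
    px = spec.pixel_size_um
    p, _p_roi = count_points(vessel_mask, effective_roi, grid, px)
    h_i, v_i = count_intersections(vessel_mask, effective_roi, grid, px)
    frame = CountingFrame(0.0, 0.0, spec.field_width_um, spec.field_height_um)
    lab = np.where(effective_roi, labelled_mask, 0)
    n = count_profiles(lab, frame, px)
    roi_area_mm2 = float(effective_roi.sum()) * px**2 * 1e-6
    counts = FieldCounts(
        points_on_vessel=p,
        intersections_h=h_i,
        intersections_v=v_i,
        profile_count=n,
        roi_area_mm2=roi_area_mm2,
        cavity_fraction=cavity_fraction,
    )
    estimates = normalize_field(counts, spec.pitch_um, cavity_threshold)
    return grid, counts, estimates
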
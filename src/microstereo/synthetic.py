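"""Synthetic vessel scenes, cohorts, and TEM thickness samples with ground truth.

Vessel profiles are modelled as ellipses produced by transversely or
obliquely sectioned cylinders: a capillary of lumen radius ``r`` cut at tilt
``θ`` yields a profile with semi-minor axis ``b = r`` and semi-major axis
``a = r / cos θ``.  Scenes carry exact analytic ground truth (profile count,
total perimeter via complete elliptic integrals, total area), so the
stereological estimators can be validated against closed forms.

Cohorts mirror the study design: groups (sham and post-injury days 2, 5,
15, 45) × thoracic segments T7–T13 × four regions (ventral/dorsal grey and
white matter) × animals × 3 replicate sections × 3 fields per section, with
region-specific baseline densities, group × segment × region reduction
multipliers, and multiplicative animal-level variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ellipe
from scipy.stats import truncnorm

from .stereology import DEFAULT_FIELD_UM, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "Ellipse",
    "VesselScene",
    "EffectModel",
    "CohortDesign",
    "sample_profiles",
    "scene_truth",
    "render",
    "render_labels",
    "simulate_cohort",
    "simulate_field_table",
    "simulate_tem",
    "TEM_GROUP_PARAMS",
    "GROUPS",
    "SEGMENTS",
    "REGIONS",
]

GROUPS = ("sham", "d2", "d5", "d15", "d45")
SEGMENTS = ("T7", "T8", "T9", "T10", "T11", "T12", "T13")
REGIONS = ("VG", "DG", "VW", "DW")

#: Mean thoracic baseline microvessel densities per region (mm^-2) and their
#: between-animal SDs, matching the intact sham cords.
BASELINE_DENSITY = {"VG": 571.0, "DG": 484.0, "VW": 90.0, "DW": 88.0}

#: Group x segment x region density multipliers relative to sham.  Printed
#: day-2 reductions: 99.2%/95.3% at the T10 epicentre (VG/DG), 47%/34% at T9,
#: 75%/62% at T11; day-45 epicentre 44%/51%.  Perilesional day-5 cells recover
#: to <25% reduction.  Remaining cells are plausible monotone-recovery
#: defaults (see docs).  Unlisted cells default to 1 (no change).
DEFAULT_MULTIPLIERS: dict[tuple[str, str, str], float] = {
    ("d2", "T9", "VG"): 0.53,
    ("d2", "T9", "DG"): 0.66,
    ("d2", "T10", "VG"): 0.008,
    ("d2", "T10", "DG"): 0.047,
    ("d2", "T11", "VG"): 0.25,
    ("d2", "T11", "DG"): 0.38,
    ("d2", "T10", "VW"): 0.15,
    ("d2", "T10", "DW"): 0.25,
    ("d5", "T9", "VG"): 0.80,
    ("d5", "T9", "DG"): 0.80,
    ("d5", "T11", "VG"): 0.80,
    ("d5", "T11", "DG"): 0.80,
    ("d5", "T10", "VG"): 0.15,
    ("d5", "T10", "DG"): 0.20,
    ("d5", "T10", "VW"): 0.30,
    ("d5", "T10", "DW"): 0.40,
    ("d15", "T10", "VG"): 0.35,
    ("d15", "T10", "DG"): 0.40,
    ("d15", "T10", "VW"): 0.60,
    ("d15", "T10", "DW"): 0.60,
    ("d45", "T10", "VG"): 0.56,
    ("d45", "T10", "DG"): 0.51,
}

#: Printed TEM thickness parameters (mean_nm, sd_nm) per
#: (group, segment, region, structure).  Only cells with published mean ± SD
#: are included.
TEM_GROUP_PARAMS: dict[tuple[str, str, str, str], tuple[float, float]] = {
    ("sham", "T10", "VG", "basement_membrane"): (34.28, 6.65),
    ("d2", "T10", "VG", "basement_membrane"): (91.08, 24.34),
    ("sham", "T10", "DG", "basement_membrane"): (29.71, 7.99),
    ("d2", "T10", "DG", "basement_membrane"): (71.21, 34.22),
    ("sham", "T10", "VG", "intercellular_cleft"): (15.52, 3.17),
    ("d2", "T10", "VG", "intercellular_cleft"): (21.91, 5.41),
    ("sham", "T10", "DG", "intercellular_cleft"): (16.28, 6.71),
    ("d2", "T10", "DG", "intercellular_cleft"): (22.69, 7.21),
    ("sham", "T11", "DG", "intercellular_cleft"): (16.00, 3.29),
    ("d2", "T11", "DG", "intercellular_cleft"): (27.28, 11.65),
}

#: Average technical-replicate counts per area per group.
TEM_N_PER_CELL = {"basement_membrane": 53, "intercellular_cleft": 33}


@dataclass(frozen=True)
class Ellipse:
    """One vessel profile: centre (μm), semi-axes a >= b (μm), orientation (rad)."""

    cx: float
    cy: float
    a: float
    b: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    @property
    def perimeter(self) -> float:
        # Complete elliptic integral of the second kind: C = 4 a E(e^2).
        m = 1.0 - (self.b / self.a) ** 2
        return 4.0 * self.a * float(ellipe(m))


@dataclass(frozen=True)
class VesselScene:
    """A field of elliptical vessel profiles with exact ground truth."""

    profiles: tuple[Ellipse, ...]
    width_um: float = DEFAULT_FIELD_UM[0]
    height_um: float = DEFAULT_FIELD_UM[1]

    @property
    def n(self) -> int:
        return len(self.profiles)


def scene_truth(scene: VesselScene) -> tuple[int, float, float]:
    """Exact (N, total perimeter μm, total area μm²) of a scene."""
    total_perimeter = sum(e.perimeter for e in scene.profiles)
    total_area = sum(e.area for e in scene.profiles)
    return scene.n, total_perimeter, total_area


@dataclass(frozen=True)
class EffectModel:
    """Statistical model of vessel-profile scenes across the cohort.

    Parameters
    ----------
    baseline_density_per_mm2
        Sham profile density per region (mm⁻²).
    radius_median_um, radius_sigma, radius_min_um
        Log-normal lumen-radius distribution (median and log-scale SD),
        left-truncated at ``radius_min_um`` (capillary lumina below ~1 μm
        are not observed and would not resolve at the default raster).
        With the tilt model below, the defaults put the population
        surface-to-volume ratio near the sham value of ~0.43 μm⁻¹.
    tilt_max_rad
        Cylinder tilt θ ~ U[0, tilt_max]; θ = 0 gives circular profiles.
    multipliers
        (group, segment, region) → density multiplier; sham is identically 1
        and unlisted cells default to 1.
    animal_sigma
        Log-scale SD of the multiplicative animal-level density effect.
    """

    baseline_density_per_mm2: dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_DENSITY)
    )
    radius_median_um: float = 2.3
    radius_sigma: float = 0.62
    radius_min_um: float = 1.0
    tilt_max_rad: float = math.pi / 3.0
    multipliers: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    animal_sigma: float = 0.07
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.baseline_density_per_mm2.values()):
            raise ValueError("baseline densities must be >= 0")
        if any(m < 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be >= 0")
        bad = [k for k, v in self.multipliers.items() if k[0] == "sham" and v != 1.0]
        if bad:
            raise ValueError(f"sham multipliers must be 1, got overrides for {bad}")

    def multiplier(self, group: str, segment: str, region: str) -> float:
        if group == "sham":
            return 1.0
        return self.multipliers.get((group, segment, region), 1.0)

    def expected_density(self, group: str, segment: str, region: str) -> float:
        return self.baseline_density_per_mm2[region] * self.multiplier(group, segment, region)


def _draw_ellipse_shape(model: EffectModel, rng: np.random.Generator) -> tuple[float, float, float]:
    r = 0.0
    while r < model.radius_min_um:  # left-truncated log-normal
        r = model.radius_median_um * math.exp(model.radius_sigma * rng.standard_normal())
    theta = rng.uniform(0.0, model.tilt_max_rad) if model.tilt_max_rad > 0 else 0.0
    b = r
    a = r / math.cos(theta)
    phi = rng.uniform(0.0, math.pi)
    return a, b, phi


def sample_profiles(
    model: EffectModel,
    group: str = "sham",
    segment: str = "T10",
    region: str = "VG",
    seed: int | None = 0,
    animal_effect: float = 1.0,
    width_um: float = DEFAULT_FIELD_UM[0],
    height_um: float = DEFAULT_FIELD_UM[1],
    max_tries: int = 200,
) -> VesselScene:
    """Draw one field of elliptical profiles for a cohort cell.

    The profile count is Poisson with mean density × field area ×
    group/segment/region multiplier × animal effect.  Profiles are placed
    uniformly, fully inside the field (so analytic ground truth matches the
    rendered mask exactly) and, unless the model allows overlap, without
    overlap by rejection on bounding circles.
    """
    rng = np.random.default_rng(seed)
    area_mm2 = width_um * height_um * 1e-6
    lam = model.expected_density(group, segment, region) * area_mm2 * animal_effect
    n = int(rng.poisson(lam))
    placed: list[Ellipse] = []
    for _ in range(n):
        for attempt in range(max_tries):
            a, b, phi = _draw_ellipse_shape(model, rng)
            if 2 * a >= min(width_um, height_um):
                continue  # profile larger than the field; redraw
            cx = rng.uniform(a, width_um - a)
            cy = rng.uniform(a, height_um - a)
            if model.allow_overlap or all(
                math.hypot(cx - e.cx, cy - e.cy) > a + e.a for e in placed
            ):
                placed.append(Ellipse(cx, cy, a, b, phi))
                break
        else:
            raise RuntimeError(
                "could not place a non-overlapping profile after "
                f"{max_tries} tries (density too high?); "
                "set allow_overlap=True on the model"
            )
    return VesselScene(profiles=tuple(placed), width_um=width_um, height_um=height_um)


def _raster_shape(scene: VesselScene, pixel_size_um: float) -> tuple[int, int]:
    return (
        int(math.ceil(scene.height_um / pixel_size_um)),
        int(math.ceil(scene.width_um / pixel_size_um)),
    )


def _paint(
    scene: VesselScene, pixel_size_um: float, out: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Set out[pixel] = values[i] for pixels whose centre is inside ellipse i."""
    h, w = out.shape
    for i, e in enumerate(scene.profiles):
        bound = e.a
        j0 = max(int((e.cx - bound) / pixel_size_um) - 1, 0)
        j1 = min(int((e.cx + bound) / pixel_size_um) + 2, w)
        i0 = max(int((e.cy - bound) / pixel_size_um) - 1, 0)
        i1 = min(int((e.cy + bound) / pixel_size_um) + 2, h)
        if j0 >= j1 or i0 >= i1:
            continue
        xs = (np.arange(j0, j1) + 0.5) * pixel_size_um - e.cx
        ys = (np.arange(i0, i1) + 0.5) * pixel_size_um - e.cy
        dx, dy = np.meshgrid(xs, ys)
        c, s = math.cos(e.phi), math.sin(e.phi)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        inside = (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
        out[i0:i1, j0:j1][inside] = values[i]
    return out


def _check_resolution(scene: VesselScene, pixel_size_um: float) -> None:
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    if scene.profiles:
        min_b = min(e.b for e in scene.profiles)
        if min_b / pixel_size_um < 3:
            raise ValueError(
                f"resolution too coarse: smallest semi-minor axis {min_b:.3g} um "
                f"spans fewer than 3 pixels at {pixel_size_um} um/px"
            )


def render(scene: VesselScene, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> np.ndarray:
    """Rasterise a scene to a binary mask (pixel-centre-inside rule)."""
    _check_resolution(scene, pixel_size_um)
    out = np.zeros(_raster_shape(scene, pixel_size_um), dtype=bool)
    if scene.profiles:
        _paint(scene, pixel_size_um, out, np.ones(scene.n, dtype=bool))
    return out


def render_labels(scene: VesselScene, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> np.ndarray:
    """Rasterise a scene to a uint16 label mask (profile i gets ID i + 1)."""
    _check_resolution(scene, pixel_size_um)
    if scene.n >= 2**16:
        raise ValueError("too many profiles for a 16-bit label mask")
    out = np.zeros(_raster_shape(scene, pixel_size_um), dtype=np.uint16)
    if scene.profiles:
        _paint(scene, pixel_size_um, out, np.arange(1, scene.n + 1, dtype=np.uint16))
    return out


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design: which cells exist and how many replicates each has."""

    groups: tuple[str, ...] = GROUPS
    segments: tuple[str, ...] = SEGMENTS
    regions: tuple[str, ...] = REGIONS
    animals_per_group: dict[str, int] = field(
        default_factory=lambda: {"sham": 4, "d2": 4, "d5": 4, "d15": 4, "d45": 3}
    )
    sections: int = 3
    fields: int = 3
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    #: (group, segment) → cavity fraction injected at those cells (disc mask).
    cavity_fractions: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}; valid: {GROUPS}")
        for g in self.groups:
            if self.animals_per_group.get(g, 0) < 1:
                raise ValueError(f"group {g!r} needs at least one animal")

    def n_fields_total(self) -> int:
        per_animal = len(self.segments) * len(self.regions) * self.sections * self.fields
        return sum(self.animals_per_group[g] for g in self.groups) * per_animal


def _animal_effects(
    model: EffectModel, design: CohortDesign, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    """Multiplicative log-normal animal effect per (animal_id, region), mean 1."""
    effects = {}
    s = model.animal_sigma
    for g in design.groups:
        for i in range(design.animals_per_group[g]):
            animal_id = f"{g}-a{i + 1}"
            for region in design.regions:
                z = rng.standard_normal()
                effects[(animal_id, region)] = math.exp(s * z - 0.5 * s * s)
    return effects


def _cavity_mask(shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Central disc covering the given fraction of the field."""
    h, w = shape
    radius_px = math.sqrt(fraction * h * w / math.pi)
    yy, xx = np.ogrid[:h, :w]
    return (xx - w / 2.0) ** 2 + (yy - h / 2.0) ** 2 <= radius_px**2


def simulate_cohort(
    model: EffectModel,
    design: CohortDesign,
    seed: int,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[VesselScene]]:
    """Generate a full cohort of scenes with manifest and ground-truth table.

    Returns ``(manifest, scenes)`` where row *i* of the manifest describes
    ``scenes[i]`` (sample key, per-field seed, cavity fraction and exact
    ground truth).  When *outdir* is given, vessel/label/ROI (and cavity)
    masks are written as TIFFs and the manifest gains their relative paths.
    Fully reproducible for a fixed seed.
    """
    root = np.random.SeedSequence(seed)
    ss_animal, ss_fields = root.spawn(2)
    effects = _animal_effects(model, design, np.random.default_rng(ss_animal))
    field_area_mm2 = DEFAULT_FIELD_UM[0] * DEFAULT_FIELD_UM[1] * 1e-6

    if outdir is not None:
        import tifffile

        outdir = Path(outdir)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)

    rows = []
    scenes: list[VesselScene] = []
    child_seeds = ss_fields.spawn(design.n_fields_total())
    idx = 0
    for g in design.groups:
        for i in range(design.animals_per_group[g]):
            animal_id = f"{g}-a{i + 1}"
            for segment in design.segments:
                for region in design.regions:
                    for section in range(1, design.sections + 1):
                        for fld in range(1, design.fields + 1):
                            scene_seed = int(child_seeds[idx].generate_state(1)[0] % 2**31)
                            idx += 1
                            scene = sample_profiles(
                                model,
                                group=g,
                                segment=segment,
                                region=region,
                                seed=scene_seed,
                                animal_effect=effects[(animal_id, region)],
                            )
                            n, per, ar = scene_truth(scene)
                            cav_frac = design.cavity_fractions.get((g, segment), 0.0)
                            row = {
                                "animal_id": animal_id,
                                "group": g,
                                "segment": segment,
                                "region": region,
                                "section_replicate": section,
                                "field_replicate": fld,
                                "scene_seed": scene_seed,
                                "cavity_fraction_injected": cav_frac,
                                "true_n": n,
                                "true_perimeter_um": per,
                                "true_area_um2": ar,
                                "true_density_per_mm2": n / field_area_mm2,
                            }
                            if outdir is not None:
                                stem = (
                                    f"{animal_id}_{segment}_{region}"
                                    f"_s{section}_f{fld}"
                                )
                                px = design.pixel_size_um
                                vessel = render(scene, px)
                                labels = render_labels(scene, px)
                                roi = np.ones_like(vessel, dtype=bool)
                                paths = {
                                    "vessel_mask": f"masks/{stem}_vessel.tif",
                                    "labelled_mask": f"masks/{stem}_labels.tif",
                                    "roi_mask": f"masks/{stem}_roi.tif",
                                }
                                tifffile.imwrite(
                                    outdir / paths["vessel_mask"],
                                    vessel.astype(np.uint8) * 255,
                                )
                                tifffile.imwrite(outdir / paths["labelled_mask"], labels)
                                tifffile.imwrite(
                                    outdir / paths["roi_mask"], roi.astype(np.uint8) * 255
                                )
                                if cav_frac > 0:
                                    cav = _cavity_mask(vessel.shape, cav_frac)
                                    paths["cavity_mask"] = f"masks/{stem}_cavity.tif"
                                    tifffile.imwrite(
                                        outdir / paths["cavity_mask"],
                                        cav.astype(np.uint8) * 255,
                                    )
                                else:
                                    paths["cavity_mask"] = ""
                                row.update(paths)
                            rows.append(row)
                            scenes.append(scene)
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        manifest.to_csv(outdir / "manifest.csv", index=False)
        truth_cols = [
            "animal_id", "group", "segment", "region", "section_replicate",
            "field_replicate", "true_n", "true_perimeter_um", "true_area_um2",
            "true_density_per_mm2",
        ]
        manifest[truth_cols].to_csv(outdir / "truth.csv", index=False)
    return manifest, scenes


def simulate_field_table(model: EffectModel, design: CohortDesign, seed: int) -> pd.DataFrame:
    """Fast per-field density table (Poisson counts only, no rasterisation).

    Used for statistical calibration and power studies where only the
    count noise structure matters; the rendered pipeline is exercised by
    `simulate_cohort` + the stereology module.
    """
    root = np.random.SeedSequence(seed)
    ss_animal, ss_counts = root.spawn(2)
    effects = _animal_effects(model, design, np.random.default_rng(ss_animal))
    rng = np.random.default_rng(ss_counts)
    field_area_mm2 = DEFAULT_FIELD_UM[0] * DEFAULT_FIELD_UM[1] * 1e-6
    rows = []
    for g in design.groups:
        for i in range(design.animals_per_group[g]):
            animal_id = f"{g}-a{i + 1}"
            for segment in design.segments:
                for region in design.regions:
                    lam = (
                        model.expected_density(g, segment, region)
                        * field_area_mm2
                        * effects[(animal_id, region)]
                    )
                    counts = rng.poisson(lam, size=design.sections * design.fields)
                    k = 0
                    for section in range(1, design.sections + 1):
                        for fld in range(1, design.fields + 1):
                            rows.append(
                                {
                                    "animal_id": animal_id,
                                    "group": g,
                                    "segment": segment,
                                    "region": region,
                                    "section_replicate": section,
                                    "field_replicate": fld,
                                    "vessel_density_per_mm2": counts[k] / field_area_mm2,
                                    "missing": False,
                                }
                            )
                            k += 1
    return pd.DataFrame(rows)


def simulate_tem(
    params: dict[tuple[str, str, str, str], tuple[float, float]] | None = None,
    n_per_cell: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample TEM thickness measurements per (group, segment, region, structure).

    Thicknesses are truncated-normal (at 0) draws at the cell's mean ± SD,
    distributed over capillaries so that every capillary satisfies the
    minimum-measurement rule (≥4 basement-membrane, ≥2 cleft measurements).
    """
    params = TEM_GROUP_PARAMS if params is None else params
    n_per_cell = TEM_N_PER_CELL if n_per_cell is None else n_per_cell
    rng = np.random.default_rng(seed)
    per_capillary = {"basement_membrane": 6, "intercellular_cleft": 3}
    rows = []
    for (group, segment, region, structure), (mu, sd) in sorted(params.items()):
        n = n_per_cell[structure]
        if sd > 0:
            a = (0.0 - mu) / sd
            values = truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)
        else:
            values = np.full(n, mu)
        n_cap = max(1, round(n / per_capillary[structure]))
        cap_of = np.sort(np.arange(n) % n_cap)
        for k, v in enumerate(values):
            rows.append(
                {
                    "thickness_nm": float(v),
                    "structure": structure,
                    "capillary_id": f"{group}_{segment}_{region}_c{cap_of[k] + 1}",
                    "segment": segment,
                    "region": region,
                    "group": group,
                    "sample_index": k,
                }
            )
    return pd.DataFrame(rows)
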
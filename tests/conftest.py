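import numpy as np
import pandas as pd
import pytest

from microstereo import Ellipse, GridSpec, VesselScene, render


@pytest.fixture
def default_spec() -> GridSpec:
    return GridSpec()


def disc_scene(cx: float, cy: float, r: float, **kwargs) -> VesselScene:
    return VesselScene((Ellipse(cx, cy, r, r),), **kwargs)


@pytest.fixture
def disc40():
    """A 40 um-radius disc rendered at the default resolution, with full ROI."""
    scene = disc_scene(150.0, 200.0, 40.0)
    mask = render(scene)
    return scene, mask, np.ones_like(mask)


def isotropic_ellipse_scene(n: int, seed: int, width=318.0, height=429.0) -> VesselScene:
    """n non-overlapping ellipses with isotropic orientations, fully inside."""
    rng = np.random.default_rng(seed)
    placed = []
    while len(placed) < n:
        r = rng.uniform(3.0, 8.0)
        a = r * rng.uniform(1.0, 2.0)
        cx = rng.uniform(a, width - a)
        cy = rng.uniform(a, height - a)
        if all((cx - e.cx) ** 2 + (cy - e.cy) ** 2 > (a + e.a) ** 2 for e in placed):
            placed.append(Ellipse(cx, cy, a, r, rng.uniform(0, np.pi)))
    return VesselScene(tuple(placed), width_um=width, height_um=height)


def animal_table(cells: dict[tuple[str, str, str], list[float]],
                 value_col: str = "vessel_density_per_mm2") -> pd.DataFrame:
    """Build a per-animal table from {(group, segment, region): [values]}."""
    rows = []
    for (g, s, r), values in cells.items():
        for i, v in enumerate(values):
            rows.append({"group": g, "segment": s, "region": r,
                         "animal_id": f"{g}-a{i + 1}", value_col: v})
    return pd.DataFrame(rows)
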
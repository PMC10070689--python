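"""File I/O: cohort manifests, tidy CSV tables with provenance headers, config.

Every table written by the pipeline carries a single ``#``-prefixed header
line recording the package version, the run seed and a hash of the
configuration, so any deterministic stage can be re-run and byte-compared.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .synthetic import GROUPS, REGIONS, SEGMENTS

__all__ = [
    "RunConfig",
    "read_manifest",
    "write_table",
    "read_table",
    "config_hash",
]

MANIFEST_KEY_COLUMNS = [
    "animal_id", "group", "segment", "region", "section_replicate", "field_replicate",
]
MANIFEST_PATH_COLUMNS = ["vessel_mask", "labelled_mask", "roi_mask"]


@dataclass
class RunConfig:
    """Flat run configuration shared by the pipeline stages."""

    pitch_um: float = 12.25
    field_width_um: float = 318.0
    field_height_um: float = 429.0
    pixel_size_um: float | None = 0.33
    cavity_threshold: float = 0.95
    seed: int = 0
    # synthetic-cohort design
    groups: list[str] = field(default_factory=lambda: list(GROUPS))
    segments: list[str] = field(default_factory=lambda: list(SEGMENTS))
    regions: list[str] = field(default_factory=lambda: list(REGIONS))
    animals_per_group: dict[str, int] = field(
        default_factory=lambda: {"sham": 4, "d2": 4, "d5": 4, "d15": 4, "d45": 3}
    )
    sections: int = 3
    fields: int = 3
    # statistics options
    posthoc_vs_sham_only: bool = True
    tem_level: str = "measurement"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(known)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a tidy CSV with a one-line provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"microstereo": __version__, **(meta or {})}
    with open(path, "w", newline="") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (table, metadata)."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("# ").strip())
            except json.JSONDecodeError:
                meta = {}
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    return df, meta


def read_manifest(
    path: str | Path,
    base_dir: str | Path | None = None,
    check_files: bool = True,
) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Required columns: the sample key (animal_id, group, segment, region,
    section_replicate, field_replicate) plus vessel/labelled/ROI mask paths;
    ``cavity_mask`` is optional and may be blank.  Enumerations are checked,
    duplicate keys rejected, and (by default) every referenced mask file
    must exist.  Paths are resolved relative to *base_dir* (default: the
    manifest's directory).
    """
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in MANIFEST_KEY_COLUMNS + MANIFEST_PATH_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest is missing required columns: {missing_cols}")
    if "cavity_mask" not in df.columns:
        df["cavity_mask"] = ""
    df["cavity_mask"] = df["cavity_mask"].fillna("")

    for col, valid in (("group", GROUPS), ("segment", SEGMENTS), ("region", REGIONS)):
        bad = sorted(set(df[col]) - set(valid))
        if bad:
            raise ValueError(f"unknown {col} token(s) {bad}; valid {col}s: {set(valid)}")
    for col in ("section_replicate", "field_replicate"):
        bad_rows = df.index[~df[col].isin([1, 2, 3])].tolist()
        if bad_rows:
            raise ValueError(f"{col} must be in 1..3; offending rows: {bad_rows}")

    dupes = df[df.duplicated(MANIFEST_KEY_COLUMNS, keep=False)]
    if not dupes.empty:
        keys = dupes[MANIFEST_KEY_COLUMNS].drop_duplicates().to_dict("records")
        raise ValueError(f"duplicate sample keys in manifest: {keys}")

    if check_files:
        for col in MANIFEST_PATH_COLUMNS + ["cavity_mask"]:
            for row_idx, rel in df[col].items():
                if col == "cavity_mask" and rel == "":
                    continue
                full = base / str(rel)
                if not full.exists():
                    raise FileNotFoundError(
                        f"manifest row {row_idx}: {col} file not found: {full}"
                    )
    return df
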
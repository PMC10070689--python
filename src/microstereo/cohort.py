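"""Hierarchical aggregation and group statistics over the cohort.

Field estimates are averaged fields → sections → animal (means of means, so
replicate sections are weighted equally), missing fields excluded from the
denominators.  The statistical stage mirrors the study's reporting: a
Shapiro–Wilk normality gate, two-way (group × segment) ANOVA with Tukey
post-hoc contrasts for the stereology read-outs, and Kruskal–Wallis with
Dunn's post-hoc test for TEM thickness data, reported as
``[F(df_interaction, df_within) = F, p = p]`` and ``[H(df) = H, p = p]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .synthetic import GROUPS, REGIONS, SEGMENTS

__all__ = [
    "SampleKey",
    "StatResult",
    "ESTIMATE_COLUMNS",
    "aggregate_to_animal",
    "normality_gate",
    "anova_tukey",
    "kruskal_dunn",
    "percent_decrease_map",
    "white_grey_ratio",
    "format_stat",
]

ESTIMATE_COLUMNS = (
    "vessel_density_per_mm2",
    "surface_density_um_per_mm2",
    "areal_density_um2_per_mm2",
    "surface_to_volume_per_um",
)

#: Star thresholds used for significance annotation.
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class SampleKey:
    """Identity of one field in the sampling hierarchy."""

    animal_id: str
    group: str
    segment: str
    region: str
    section_replicate: int
    field_replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; valid: {GROUPS}")
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}; valid: {SEGMENTS}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; valid: {REGIONS}")
        for name in ("section_replicate", "field_replicate"):
            v = getattr(self, name)
            if v not in (1, 2, 3):
                raise ValueError(f"{name} must be in 1..3, got {v}")


@dataclass(frozen=True)
class StatResult:
    """Result of one omnibus test with its post-hoc contrasts.

    ``df`` is ``(df_interaction, df_within)`` for the two-way ANOVA and a
    one-tuple ``(k - 1,)`` for Kruskal–Wallis.  Each post-hoc entry is
    ``(contrast_label, adjusted_p)``.
    """

    test: str  # "anova2" | "kruskal"
    statistic: float
    df: tuple[int, ...]
    p_value: float
    posthoc: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValueError(f"degrees of freedom must be positive, got {self.df}")


def format_stat(result: StatResult) -> str:
    """Render a result in the study's reporting format."""
    if result.test == "anova2":
        head = f"[F({result.df[0]}, {result.df[1]}) = {result.statistic:.3f}"
    else:
        head = f"[H({result.df[0]}) = {result.statistic:.4g}"
    p = result.p_value
    p_str = "p < 0.0001" if p < 1e-4 else f"p = {p:.4g}"
    return f"{head}, {p_str}]"


def stars(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


def aggregate_to_animal(
    fields: pd.DataFrame,
    value_cols: tuple[str, ...] = ESTIMATE_COLUMNS,
) -> pd.DataFrame:
    """Per-animal means by (group, segment, region): fields → sections → animal.

    Missing fields (NaN values, or rows flagged ``missing``) are excluded
    from every denominator; animal-cells with no non-missing field are
    absent from the output.
    """
    df = fields.copy()
    if "missing" in df.columns:
        df.loc[df["missing"].astype(bool), list(value_cols)] = np.nan
    keys = ["group", "segment", "region", "animal_id"]
    section_means = df.groupby(keys + ["section_replicate"], as_index=False)[
        list(value_cols)
    ].mean()
    animal_means = section_means.groupby(keys, as_index=False)[list(value_cols)].mean()
    all_nan = animal_means[list(value_cols)].isna().all(axis=1)
    return animal_means[~all_nan].reset_index(drop=True)


def normality_gate(
    df: pd.DataFrame,
    value_col: str,
    by: tuple[str, ...] = ("group", "segment", "region"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Shapiro–Wilk test per cell; flags are surfaced, not used to switch tests.

    The downstream pipeline applies the study's fixed test choices (ANOVA
    for stereology, Kruskal–Wallis for TEM) regardless of the flag.  Cells
    with fewer than 3 values, or constant values, are flagged ``untestable``.
    """
    rows = []
    for key, sub in df.groupby(list(by)):
        values = sub[value_col].dropna().to_numpy()
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        if len(values) < 3 or np.ptp(values) == 0:
            row.update(shapiro_w=np.nan, shapiro_p=np.nan, flag="untestable")
        else:
            w, p = stats.shapiro(values)
            row.update(
                shapiro_w=float(w),
                shapiro_p=float(p),
                flag="non-normal" if p < alpha else "normal",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def anova_tukey(
    animal_df: pd.DataFrame,
    value_col: str,
    posthoc: bool = True,
    vs_sham_only: bool = True,
) -> StatResult:
    """Two-way (group × segment) ANOVA with Tukey post-hoc contrasts.

    Fits ``value ~ group * segment`` with sum-to-zero contrasts and type-III
    sums of squares so unbalanced designs (the n = 3 day-45 group,
    cavity-induced missing cells) are handled by dropping, not imputing.
    Reports the interaction F with (df_interaction, df_within).  Post-hoc:
    Tukey-adjusted pairwise group comparisons within each segment,
    restricted to group-vs-sham contrasts unless ``vs_sham_only=False``.
    """
    df = animal_df.dropna(subset=[value_col]).copy()
    groups = sorted(df["group"].unique())
    segments = sorted(df["segment"].unique())
    if len(groups) < 2 or len(segments) < 2:
        raise ValueError("need at least 2 groups and 2 segments for a two-way ANOVA")
    cell_n = df.groupby(["group", "segment"]).size()
    empty = [
        (g, s) for g in groups for s in segments if (g, s) not in cell_n.index
    ]
    if empty:
        raise ValueError(f"empty design cells prevent estimation: {empty}")
    model = ols(
        f"Q('{value_col}') ~ C(group, Sum) * C(segment, Sum)", data=df
    ).fit()
    table = anova_lm(model, typ=3)
    inter_row = table.loc["C(group, Sum):C(segment, Sum)"]
    resid_row = table.loc["Residual"]
    df_inter = int(round(inter_row["df"]))
    df_within = int(round(resid_row["df"]))
    f_value = float(inter_row["F"])
    p_value = float(inter_row["PR(>F)"])
    contrasts: list[tuple[str, float]] = []
    if posthoc:
        for segment in segments:
            sub = df[df["segment"] == segment]
            if sub["group"].nunique() < 2 or sub.groupby("group").size().min() < 2:
                continue
            hsd = pairwise_tukeyhsd(sub[value_col].to_numpy(), sub["group"].to_numpy())
            res = hsd.summary().data[1:]
            for g1, g2, _meandiff, p_adj, *_ in res:
                if vs_sham_only and "sham" not in (g1, g2):
                    continue
                contrasts.append((f"{segment}: {g1} vs {g2}", float(p_adj)))
    return StatResult(
        test="anova2",
        statistic=f_value,
        df=(df_inter, df_within),
        p_value=p_value,
        posthoc=tuple(contrasts),
    )


def kruskal_dunn(
    df: pd.DataFrame,
    value_col: str,
    cell_cols: tuple[str, ...] = ("group",),
    adjust: str = "bonferroni",
) -> StatResult:
    """Kruskal–Wallis over group×location cells with Dunn's post-hoc test.

    Each combination of *cell_cols* defines one sample; H is reported with
    ``df = k − 1``.  Dunn's test compares mean ranks of the pooled ranking
    with a tie-corrected normal approximation and adjusts the pairwise
    p-values (Bonferroni by default, as in Dunn's original procedure).
    """
    data = df.dropna(subset=[value_col])
    labels = data[list(cell_cols)].astype(str).agg("/".join, axis=1)
    samples = {lab: sub[value_col].to_numpy() for lab, sub in data.groupby(labels)}
    samples = {lab: v for lab, v in samples.items() if len(v) >= 2}
    if len(samples) < 2:
        raise ValueError("need at least 2 cells with >= 2 values each")
    values = [np.asarray(v, dtype=float) for v in samples.values()]
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate data: all values tied across cells")
    h, p = stats.kruskal(*values)
    k = len(samples)

    # Dunn's z statistics on pooled mean ranks with tie correction.
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    splits = np.cumsum([len(v) for v in values])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = {lab: rg.mean() for lab, rg in zip(samples, rank_groups)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    names, raw_p = [], []
    for lab_i, lab_j in combinations(samples, 2):
        ni, nj = len(samples[lab_i]), len(samples[lab_j])
        se = np.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[lab_i] - mean_ranks[lab_j]) / se
        names.append(f"{lab_i} vs {lab_j}")
        raw_p.append(2.0 * stats.norm.sf(abs(z)))
    adj_p = multipletests(raw_p, method=adjust)[1]
    return StatResult(
        test="kruskal",
        statistic=float(h),
        df=(k - 1,),
        p_value=float(p),
        posthoc=tuple(zip(names, (float(q) for q in adj_p))),
    )


def percent_decrease_map(
    animal_df: pd.DataFrame,
    value_col: str = "vessel_density_per_mm2",
    decimals: int = 1,
) -> pd.DataFrame:
    """Percent decrease vs the sham mean per (group, segment, region).

    ``100 × (sham − group) / sham``; negative entries indicate increases.
    Cells without a sham mean are absent.
    """
    means = (
        animal_df.dropna(subset=[value_col])
        .groupby(["group", "segment", "region"], as_index=False)[value_col]
        .mean()
    )
    sham = means[means["group"] == "sham"].set_index(["segment", "region"])[value_col]
    rows = []
    for _, row in means[means["group"] != "sham"].iterrows():
        key = (row["segment"], row["region"])
        if key not in sham.index or not sham[key] > 0:
            continue
        dec = 100.0 * (sham[key] - row[value_col]) / sham[key]
        rows.append(
            {
                "group": row["group"],
                "segment": row["segment"],
                "region": row["region"],
                "percent_decrease": round(float(dec), decimals),
            }
        )
    return pd.DataFrame(rows, columns=["group", "segment", "region", "percent_decrease"])


def white_grey_ratio(
    sham_animal_df: pd.DataFrame,
    value_col: str = "vessel_density_per_mm2",
) -> float:
    """White-matter density as a percentage of grey-matter density (sham).

    ``100 × mean(VW, DW) / mean(VG, DG)`` over sham region means, one
    decimal place.
    """
    df = sham_animal_df
    if "group" in df.columns:
        df = df[df["group"] == "sham"]
    region_means = df.dropna(subset=[value_col]).groupby("region")[value_col].mean()
    missing = [r for r in REGIONS if r not in region_means.index]
    if missing:
        raise ValueError(f"missing sham region means for {missing}")
    white = (region_means["VW"] + region_means["DW"]) / 2.0
    grey = (region_means["VG"] + region_means["DG"]) / 2.0
    return round(100.0 * white / grey, 1)
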
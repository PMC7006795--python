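"""Vegetation-plot selection and per-plot abundance quantities.

Plots are handled as long-format :class:`pandas.DataFrame` tables with one
row per (plot, species) cover record and the columns

``plot_id, latitude, longitude, area_m2, tree_layer_cover, continent,
species_id, cover, woody, alien_here``

where ``cover`` is percent canopy cover (> 0), ``woody`` flags woody
species and ``alien_here`` flags species that are alien in the plot's
region. Forest plots are retained when they have at least 25% tree-layer
cover, at least three woody species and an area of at least 100 m^2; the
richness floor guards against plantation plots, the area floor against
plots with too few woody individuals for community-level metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PLOT_COLUMNS = [
    "plot_id",
    "latitude",
    "longitude",
    "area_m2",
    "tree_layer_cover",
    "continent",
    "species_id",
    "cover",
    "woody",
    "alien_here",
]

#: per-plot metadata columns (constant within a plot)
PLOT_META = ["latitude", "longitude", "area_m2", "tree_layer_cover", "continent"]


class PlotValidationError(ValueError):
    """A plot table violates the input contract (names the offending plots)."""


@dataclass(frozen=True)
class FocalSpecies:
    """A candidate focal species and its range information.

    ``native_continents`` are the continents of the species' native range;
    after filtering, native and alien plots lie on disjoint continents.
    ``invasive`` carries the invasive / non-invasive classification and is
    a pass-through label, never inferred here.
    """

    species_id: str
    native_continents: frozenset = field(default_factory=frozenset)
    invasive: bool | None = None


def validate_plot_table(plots: pd.DataFrame) -> None:
    """Check schema and basic invariants of a long-format plot table."""
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise PlotValidationError(f"plot table missing columns: {missing}")
    for col in ("area_m2", "tree_layer_cover"):
        bad = plots.loc[plots[col].isna(), "plot_id"].unique()
        if len(bad):
            raise PlotValidationError(
                f"plots with missing {col}: {sorted(map(str, bad))}"
            )
    if (plots["cover"] <= 0).any():
        bad = plots.loc[plots["cover"] <= 0, "plot_id"].unique()
        raise PlotValidationError(
            f"non-positive cover records in plots: {sorted(map(str, bad))}"
        )
    lat = plots["latitude"]
    if ((lat < -90) | (lat > 90)).any():
        bad = plots.loc[(lat < -90) | (lat > 90), "plot_id"].unique()
        raise PlotValidationError(f"latitude out of range in plots: {sorted(map(str, bad))}")


def woody_richness(plot: pd.DataFrame) -> int:
    """Number of distinct woody species with cover > 0 in one plot's records.

    A species recorded in several vegetation layers counts once.
    """
    rec = plot[(plot["woody"]) & (plot["cover"] > 0)]
    return int(rec["species_id"].nunique())


def filter_plots(
    plots: pd.DataFrame,
    min_tree_cover: float = 25.0,
    min_woody_richness: int = 3,
    min_area: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the forest / richness / area selection rules.

    Thresholds are inclusive minima. Returns ``(retained, removal_log)``
    where the log has one row per removed plot with columns
    ``plot_id, rule`` and rule one of ``tree_cover | woody_richness |
    area`` (the first violated rule, in that order). Input row order is
    preserved for retained plots.
    """
    validate_plot_table(plots)
    meta = plots.groupby("plot_id", sort=False).first()
    richness = (
        plots[(plots["woody"]) & (plots["cover"] > 0)]
        .groupby("plot_id")["species_id"]
        .nunique()
        .reindex(meta.index, fill_value=0)
    )
    removed: list[tuple[object, str]] = []
    keep_ids = []
    for pid, row in meta.iterrows():
        if row["tree_layer_cover"] < min_tree_cover:
            removed.append((pid, "tree_cover"))
        elif richness[pid] < min_woody_richness:
            removed.append((pid, "woody_richness"))
        elif row["area_m2"] < min_area:
            removed.append((pid, "area"))
        else:
            keep_ids.append(pid)
    log = pd.DataFrame(removed, columns=["plot_id", "rule"])
    retained = plots[plots["plot_id"].isin(keep_ids)].reset_index(drop=True)
    return retained, log


def infer_native_continents(plots: pd.DataFrame, species_id: str) -> frozenset:
    """Continents where the species occurs as a native (``alien_here`` False)."""
    rec = plots[(plots["species_id"] == species_id) & (~plots["alien_here"])]
    return frozenset(rec["continent"].unique())


def exclude_same_continent_alien_plots(
    plots: pd.DataFrame, focal: FocalSpecies
) -> pd.DataFrame:
    """Drop plots where the focal species is alien on one of its native continents.

    Keeps the focal species' native and alien ranges on different
    continents so that between-range contrasts reflect genuinely distinct
    abiotic and biotic settings. Plots not containing the focal species
    pass through unchanged.
    """
    if plots["continent"].isna().any():
        bad = plots.loc[plots["continent"].isna(), "plot_id"].unique()
        raise PlotValidationError(f"plots with unknown continent: {sorted(map(str, bad))}")
    native = focal.native_continents or infer_native_continents(plots, focal.species_id)
    is_focal_alien = (plots["species_id"] == focal.species_id) & plots["alien_here"]
    offending = plots.loc[
        is_focal_alien & plots["continent"].isin(native), "plot_id"
    ].unique()
    return plots[~plots["plot_id"].isin(offending)].reset_index(drop=True)


def relative_abundance(plot: pd.DataFrame, focal_species: str) -> float:
    """Focal species' share of total woody cover in one plot, in (0, 1].

    Non-woody species never enter the denominator. Layered records of the
    same species contribute their summed cover.
    """
    woody = plot[(plot["woody"]) & (plot["cover"] > 0)]
    focal_cover = woody.loc[woody["species_id"] == focal_species, "cover"].sum()
    if focal_cover <= 0:
        raise ValueError(
            f"focal species {focal_species!r} absent or non-woody in plot"
        )
    return float(focal_cover / woody["cover"].sum())


def range_label(plot: pd.DataFrame, focal_species: str) -> str:
    """``'alien'`` if the focal species is flagged alien in this plot, else ``'native'``."""
    rec = plot[plot["species_id"] == focal_species]
    if rec.empty:
        raise ValueError(f"focal species {focal_species!r} absent from plot")
    return "alien" if bool(rec["alien_here"].iloc[0]) else "native"


def select_focal_species(
    plots: pd.DataFrame,
    candidates: list[FocalSpecies],
    min_plots_per_range: int = 3,
) -> list[FocalSpecies]:
    """Keep candidates occurring in >= ``min_plots_per_range`` plots per range."""
    kept = []
    for focal in candidates:
        rec = plots[plots["species_id"] == focal.species_id]
        n_alien = rec.loc[rec["alien_here"], "plot_id"].nunique()
        n_native = rec.loc[~rec["alien_here"], "plot_id"].nunique()
        if n_native >= min_plots_per_range and n_alien >= min_plots_per_range:
            kept.append(focal)
    return kept
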
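"""Community trait metrics for focal-species x plot observations.

Four traits describe each woody species: specific leaf area (SLA,
cm^2/g), adult height (H, m), seed mass (SM, mg) and wood density
(WD, g/cm^3). All metrics operate on natural-log trait values; logging
tames the heavy right tails of SLA, H and SM.

For a focal species in a plot, the community reference is the
cover-weighted mean (CWM) of the ln traits of co-occurring woody
species. From focal ln traits ``f`` and CWM ``c``:

* multivariate dissimilarity (Gower over 4 continuous traits):
  ``d = (1/4) * sum_t |f_t - c_t| / R_t`` with ``R_t`` the ln-trait
  range over the analysed species set; 0 = functionally identical,
  1 = maximally distinct. Similarity is ``1 - d``.
* competitive trait differences: ``delta_t = f_t - c_t``; positive means
  the focal species exceeds its community's mean trait value.

Community weighting excludes the focal species itself, and excludes
alien species (other than the focal, which is excluded anyway) in both
ranges, so the reference community is the resident native woody flora.
Gymnosperms and angiosperms are both retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = ["sla", "height", "sm", "wd"]
TRAIT_CSV_COLUMNS = {
    "sla": "sla_cm2_g",
    "height": "height_m",
    "sm": "seed_mass_mg",
    "wd": "wood_density_g_cm3",
}

ANALYSIS_ROW_COLUMNS = [
    "focal_species",
    "plot_id",
    "range",
    "rel_abund",
    "dissim",
    "d_sla",
    "d_height",
    "d_sm",
    "d_wd",
    "hii",
    "spei",
    "richness",
]


class TraitError(ValueError):
    pass


def log_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Natural-log trait table indexed by species.

    Accepts either the CSV column names (``sla_cm2_g`` etc.) or already
    short names; requires strictly positive raw values.
    """
    df = traits.copy()
    if "species_id" in df.columns:
        df = df.set_index("species_id")
    rename = {v: k for k, v in TRAIT_CSV_COLUMNS.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [t for t in TRAITS if t not in df.columns]
    if missing:
        raise TraitError(f"trait table missing columns: {missing}")
    df = df[TRAITS]
    if (df <= 0).any().any():
        bad = df.index[(df <= 0).any(axis=1)]
        raise TraitError(f"non-positive trait values for species: {list(bad)}")
    return np.log(df)


@dataclass(frozen=True)
class TraitRanges:
    """Per-trait max - min of ln trait values over the reference species set.

    Computed once per dataset over all species appearing in analysed
    plots, so that dissimilarities are comparable across plots.
    """

    ranges: np.ndarray  # shape (4,), ordered as TRAITS

    def __post_init__(self):
        r = np.asarray(self.ranges, dtype=float)
        if r.shape != (4,) or not (r > 0).all():
            raise TraitError(f"trait ranges must be 4 positive values, got {r}")
        object.__setattr__(self, "ranges", r)


def trait_ranges(ln_traits: pd.DataFrame, species_subset=None) -> TraitRanges:
    """Observed ln-trait ranges over ``species_subset`` (default: all rows)."""
    sub = ln_traits if species_subset is None else ln_traits.loc[list(species_subset)]
    if len(sub) < 2:
        raise TraitError("need at least two species to define trait ranges")
    r = (sub.max() - sub.min()).to_numpy(dtype=float)
    if (r <= 0).any():
        degenerate = [t for t, v in zip(TRAITS, r) if v <= 0]
        raise TraitError(f"degenerate (zero-range) traits: {degenerate}")
    return TraitRanges(r)


def community_weights(
    plot: pd.DataFrame, focal: str, range_of_plot: str
) -> dict[str, float]:
    """Cover weights over eligible co-occurring woody species.

    Eligible species are woody, not the focal itself, and not alien in
    the plot (alien neighbours are excluded in both native- and
    alien-range plots). Weights are proportional to summed cover and sum
    to 1. Returns an empty dict when no neighbour is eligible; callers
    drop and log such rows.
    """
    if range_of_plot not in ("native", "alien"):
        raise ValueError(f"range must be 'native' or 'alien', got {range_of_plot!r}")
    elig = plot[
        (plot["woody"])
        & (plot["cover"] > 0)
        & (plot["species_id"] != focal)
        & (~plot["alien_here"])
    ]
    if elig.empty:
        return {}
    cover = elig.groupby("species_id")["cover"].sum()
    w = cover / cover.sum()
    return {str(k): float(v) for k, v in w.items()}


def cwm_log_traits(
    weights: dict[str, float], ln_traits: pd.DataFrame
) -> tuple[np.ndarray, dict[str, float]]:
    """Abundance-weighted mean ln-trait vector of the weighted species.

    Species missing from the trait table are dropped and the remaining
    weights renormalized; the effective weights actually used are
    returned alongside. Raises :class:`TraitError` if no weighted species
    has traits.
    """
    have = {s: w for s, w in weights.items() if s in ln_traits.index}
    dropped = set(weights) - set(have)
    if dropped:
        logger.debug("species without traits dropped from CWM: %s", sorted(dropped))
    if not have:
        raise TraitError("no weighted species has trait data")
    total = sum(have.values())
    used = {s: w / total for s, w in have.items()}
    mat = ln_traits.loc[list(used)].to_numpy(dtype=float)
    wvec = np.array(list(used.values()))
    return mat.T @ wvec, used


def multivariate_dissimilarity(
    focal_lntraits: np.ndarray, cwm: np.ndarray, ranges: TraitRanges
) -> float:
    """Range-normalized Manhattan (Gower) distance between focal and CWM.

    Clipped to [0, 1] only if the CWM escapes the global trait range
    (possible when weights concentrate on a range-defining species and
    the focal sits at the opposite extreme); a warning is logged.
    """
    scaled = np.abs(np.asarray(focal_lntraits) - np.asarray(cwm)) / ranges.ranges
    d = float(scaled.mean())
    if d > 1.0:
        logger.warning("Gower dissimilarity %.4f > 1 clipped; CWM outside global range", d)
        d = 1.0
    return d


def euclidean_dissimilarity(
    focal_lntraits: np.ndarray, cwm: np.ndarray, ranges: TraitRanges
) -> float:
    """Euclidean analogue on range-scaled ln traits (used for the r > .95 check)."""
    scaled = (np.asarray(focal_lntraits) - np.asarray(cwm)) / ranges.ranges
    return float(np.sqrt((scaled**2).sum()))


def competitive_differences(focal_lntraits: np.ndarray, cwm: np.ndarray) -> np.ndarray:
    """(dSLA, dH, dSM, dWD): focal ln trait minus community-weighted mean ln trait."""
    return np.asarray(focal_lntraits, dtype=float) - np.asarray(cwm, dtype=float)


def build_analysis_rows(
    plots: pd.DataFrame,
    ln_traits: pd.DataFrame,
    focal_species: list[str],
    plot_hii: pd.Series | None = None,
    plot_spei: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the focal-species x plot analysis table.

    One row per focal species per plot where the species occurs with at
    least one eligible co-occurring woody neighbour; columns follow
    ``ANALYSIS_ROW_COLUMNS`` (plus ``dissim_eucl`` for the structural
    correlation check). ``plot_hii`` / ``plot_spei`` are per-plot
    covariates indexed by plot_id (NaN where absent). Returns
    ``(rows, skipped_log)`` where the log lists (focal, plot, reason)
    for rows that could not be formed.
    """
    from rangeabund import plot_prep

    ranges = trait_ranges(ln_traits)
    out: list[dict] = []
    skipped: list[tuple[str, object, str]] = []
    for pid, plot in plots.groupby("plot_id", sort=False):
        richness = plot_prep.woody_richness(plot)
        present = set(plot.loc[plot["woody"] & (plot["cover"] > 0), "species_id"])
        for focal in focal_species:
            if focal not in present:
                continue
            if focal not in ln_traits.index:
                skipped.append((focal, pid, "focal_missing_traits"))
                continue
            rng = plot_prep.range_label(plot, focal)
            weights = community_weights(plot, focal, rng)
            if not weights:
                skipped.append((focal, pid, "no_eligible_neighbours"))
                continue
            try:
                cwm, _ = cwm_log_traits(weights, ln_traits)
            except TraitError:
                skipped.append((focal, pid, "no_neighbour_traits"))
                continue
            f = ln_traits.loc[focal].to_numpy(dtype=float)
            delta = competitive_differences(f, cwm)
            out.append(
                {
                    "focal_species": focal,
                    "plot_id": pid,
                    "range": rng,
                    "rel_abund": plot_prep.relative_abundance(plot, focal),
                    "dissim": multivariate_dissimilarity(f, cwm, ranges),
                    "dissim_eucl": euclidean_dissimilarity(f, cwm, ranges),
                    "d_sla": delta[0],
                    "d_height": delta[1],
                    "d_sm": delta[2],
                    "d_wd": delta[3],
                    "hii": float(plot_hii.get(pid, np.nan)) if plot_hii is not None else np.nan,
                    "spei": float(plot_spei.get(pid, np.nan)) if plot_spei is not None else np.nan,
                    "richness": richness,
                }
            )
    rows = pd.DataFrame(out, columns=ANALYSIS_ROW_COLUMNS + ["dissim_eucl"])
    log = pd.DataFrame(skipped, columns=["focal_species", "plot_id", "reason"])
    return rows, log
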
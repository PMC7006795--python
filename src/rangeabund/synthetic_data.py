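"""Seeded generators for design-level and plot-level synthetic data.

Two levels, matching how the pipeline is tested:

* :func:`gen_design` simulates the hierarchical regression forward from
  known parameters (a :class:`GeneratorTruth`), producing an analysis
  table plus the latent species/plot effects — the testbed for
  parameter recovery.
* :func:`gen_plots` builds whole vegetation-plot communities (covers,
  traits, range labels, seasonal climate series, human-influence index)
  so every preparation and metric stage can run end to end without any
  external data.

The plot-level generator emulates the structure of global forest-plot
data: multi-species plots with cover fractions, correlated log-normal
traits with pairwise |r| < 0.4, focal species present in both a native
and an alien continent, sinusoidal seasonal temperature with
gamma-distributed monthly precipitation. It does not emulate dispersal,
spatial autocorrelation or realistic biogeography.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from rangeabund.hier_model import (
    EQUATIONS,
    INTERACTIONS,
    L2_COVARIATES,
    MAIN_EFFECTS,
    ModelData,
)
from rangeabund.trait_metrics import TRAIT_CSV_COLUMNS, TRAITS

#: alien share of the vegetation-plot universe the study conditions assume
#: (15,584 alien of 228,943 total plots)
ALIEN_FRACTION = 15_584 / 228_943


@dataclass
class GeneratorTruth:
    """Known parameters of the forward-simulated hierarchical model.

    ``gamma`` is (10 equations) x (intercept + 4 trait coefficients),
    equations ordered as ``hier_model.EQUATIONS``; ``delta`` follows
    ``hier_model.INTERACTIONS``.
    """

    gamma: np.ndarray
    delta: np.ndarray
    sigma_theta: np.ndarray  # (10,): intercept then the 9 slope sds
    sigma_plot: float
    sigma_resid: float
    alien_fraction: float = ALIEN_FRACTION
    n_species: int = 40
    n_plots: int = 1000
    species_per_plot: int = 5
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.sigma_theta = np.asarray(self.sigma_theta, dtype=float)
        if self.gamma.shape != (len(EQUATIONS), len(L2_COVARIATES) + 1):
            raise ValueError(f"gamma must be {(len(EQUATIONS), 5)}")
        if self.delta.shape != (len(INTERACTIONS),):
            raise ValueError("delta must have one entry per interaction")
        if not ((self.sigma_theta > 0).all() and self.sigma_plot > 0
                and self.sigma_resid > 0):
            raise ValueError("all standard deviations must be positive")
        if not 0 < self.alien_fraction < 1:
            raise ValueError("alien_fraction must be in (0, 1)")

    @property
    def n_rows(self) -> int:
        return self.n_plots * self.species_per_plot

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("gamma", "delta", "sigma_theta"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorTruth":
        return cls(**json.loads(text))


def default_truth(seed: int = 0) -> GeneratorTruth:
    """Reference truth for recovery tests.

    Signs follow the qualitative result structure the model is meant to
    detect: negative dissimilarity and richness effects, positive
    height/wood-density/seed-mass competitive differences with the
    seed-mass advantage confined to the native range (negative
    seed-mass x range interaction), SPEI mattering in the alien range
    only, trait moderation of the dSLA and dWD slopes. Magnitudes are
    invented test defaults, flagged as such in the metadata.
    """
    gamma = np.zeros((len(EQUATIONS), 5))
    g = {eq: i for i, eq in enumerate(EQUATIONS)}
    gamma[g["dissim"], 0] = -0.15
    gamma[g["d_height"], 0] = 0.10
    gamma[g["d_wd"], 0] = 0.15
    gamma[g["d_sm"], 0] = 0.08
    gamma[g["richness"], 0] = -0.20
    gamma[g["spei"], 0] = 0.02
    gamma[g["range"], 0] = -0.05
    # trait moderation of slopes: species' own SLA strengthens the dSLA
    # slope, own WD strengthens the dWD slope
    gamma[g["d_sla"], 1 + L2_COVARIATES.index("sla")] = 0.10
    gamma[g["d_wd"], 1 + L2_COVARIATES.index("wd")] = 0.10
    delta = np.zeros(len(INTERACTIONS))
    d = {k: i for i, k in enumerate(INTERACTIONS)}
    delta[d["d_sm"]] = -0.08
    delta[d["spei"]] = 0.08
    return GeneratorTruth(
        gamma=gamma,
        delta=delta,
        sigma_theta=np.concatenate([[0.30], np.full(9, 0.10)]),
        sigma_plot=0.30,
        sigma_resid=0.70,
        seed=seed,
        meta={"magnitudes": "invented default", "signs": "qualitative result structure"},
    )


def design_correlation() -> np.ndarray:
    """Correlation matrix of the 8 continuous predictors (before range).

    Mild realistic collinearity, all |r| <= 0.4: the dissimilarity index
    co-moves with the absolute trait differences, and richness is weakly
    negatively tied to the trait-difference spread.
    """
    names = [k for k in MAIN_EFFECTS if k != "range"]
    S = np.eye(len(names))
    idx = {k: i for i, k in enumerate(names)}

    def set_r(a, b, r):
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = r

    set_r("dissim", "d_sla", 0.25)
    set_r("dissim", "d_height", 0.25)
    set_r("dissim", "d_wd", 0.20)
    set_r("d_sla", "d_wd", -0.30)
    set_r("d_height", "d_sm", 0.30)
    set_r("richness", "dissim", -0.15)
    set_r("hii", "spei", 0.10)
    return S


def gen_design(truth: GeneratorTruth, seed: int | None = None) -> dict:
    """Forward-simulate the hierarchical model.

    Returns ``{"data": ModelData, "rows": DataFrame, "latents": dict,
    "truth": truth}``. Continuous predictors are drawn multivariate
    normal with unit variances (already on the standardized scale the
    model is parameterized on); the native/alien indicator is Bernoulli
    at ``truth.alien_fraction`` and standardized by its population
    moments. Latent species and plot effects are returned for oracle
    checks.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    J, P, spp = truth.n_species, truth.n_plots, truth.species_per_plot
    n = truth.n_rows

    plot_idx = np.repeat(np.arange(P), spp)
    species_idx = np.concatenate(
        [rng.choice(J, size=spp, replace=False) for _ in range(P)]
    )
    T = rng.standard_normal((J, len(L2_COVARIATES)))
    T = (T - T.mean(0)) / T.std(0)

    cont_names = [k for k in MAIN_EFFECTS if k != "range"]
    S = design_correlation()
    Xc = rng.multivariate_normal(np.zeros(len(cont_names)), S, size=n,
                                 method="cholesky")
    f = truth.alien_fraction
    alien = (rng.random(n) < f).astype(float)
    range_std = (alien - f) / np.sqrt(f * (1 - f))
    X = np.empty((n, len(MAIN_EFFECTS)))
    for k, name in enumerate(MAIN_EFFECTS):
        X[:, k] = range_std if name == "range" else Xc[:, cont_names.index(name)]
    Z = X[:, [MAIN_EFFECTS.index(k) for k in INTERACTIONS]] * range_std[:, None]

    U = np.column_stack([np.ones(J), T])
    theta = U @ truth.gamma.T + rng.standard_normal((J, len(EQUATIONS))) \
        * truth.sigma_theta[None, :]
    u = rng.normal(0.0, truth.sigma_plot, size=P)
    W = np.column_stack([np.ones(n), X])
    y = (
        np.einsum("ij,ij->i", W, theta[species_idx])
        + Z @ truth.delta
        + u[plot_idx]
        + rng.normal(0.0, truth.sigma_resid, size=n)
    )

    species_ids = [f"sp{j:03d}" for j in range(J)]
    plot_ids = [f"plot{p:05d}" for p in range(P)]
    data = ModelData(
        y=y, X=X, Z=Z, species_idx=species_idx, plot_idx=plot_idx, T=T,
        species_ids=species_ids, plot_ids=plot_ids,
    )
    rows = pd.DataFrame(X, columns=MAIN_EFFECTS)
    rows.insert(0, "plot_id", np.array(plot_ids)[plot_idx])
    rows.insert(0, "focal_species", np.array(species_ids)[species_idx])
    rows["alien"] = alien.astype(int)
    rows["y"] = y
    return {
        "data": data,
        "rows": rows,
        "latents": {"theta": theta, "u": u, "alien": alien},
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# plot-level communities
# ---------------------------------------------------------------------------

CONTINENTS = {"Eurasia": (35.0, 60.0), "Americas": (25.0, 50.0)}

#: ln-trait means/sds for SLA (cm^2/g), H (m), SM (mg), WD (g/cm^3)
TRAIT_LN_MEAN = np.array([np.log(150.0), np.log(15.0), np.log(50.0), np.log(0.55)])
TRAIT_LN_SD = np.array([0.40, 0.50, 1.20, 0.25])


def trait_correlation() -> np.ndarray:
    """Pairwise ln-trait correlations, capped below |r| = 0.4."""
    R = np.eye(4)
    R[0, 3] = R[3, 0] = -0.30  # SLA vs WD
    R[1, 2] = R[2, 1] = 0.30   # H vs SM
    return R


@dataclass
class GeneratorConfig:
    """Knobs of the plot-level community generator."""

    n_species_pool: int = 60
    n_focal: int = 10
    n_plots: int = 160
    richness_mean: float = 5.0        # woody richness = 3 + Poisson(mean)
    dirichlet_conc: float = 1.0
    p_focal_native: float = 0.45      # focal inclusion prob, native continent
    p_focal_alien: float = 0.25       # focal inclusion prob, alien continent
    p_alien_contaminant: float = 0.10  # chance of a non-focal alien record
    p_herb_plot: float = 0.30         # chance a plot carries herb records
    n_years_climate: int = 30
    min_range_plots: int = 4          # forced focal presence per range
    seed: int = 0


def _community_covers(k: int, conc: float, rng) -> np.ndarray:
    total = rng.uniform(40.0, 95.0)
    frac = rng.dirichlet(np.full(k, conc))
    return np.clip(frac * total, 0.05, None)


def gen_plots(config: GeneratorConfig | None = None) -> dict:
    """Generate a full plot-level dataset.

    Returns a dict with ``plots`` (long-format plot table), ``traits``
    (trait CSV schema), ``climate`` (monthly series per plot), ``hii``
    (per-plot Series), ``focal_species`` (ids) and ``config``. Every
    plot passes the forest/richness/area filters by construction, and
    every focal species is present in at least ``min_range_plots`` plots
    on each of its native and alien continents.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    continents = list(CONTINENTS)

    pool = [f"sp{j:03d}" for j in range(cfg.n_species_pool)]
    native_cont = {s: continents[j % 2] for j, s in enumerate(pool)}
    focal = pool[: cfg.n_focal]
    herbs = [f"herb{j:02d}" for j in range(12)]

    # correlated log-normal traits for every woody species
    L = np.linalg.cholesky(trait_correlation())
    lnT = TRAIT_LN_MEAN + (rng.standard_normal((len(pool), 4)) @ L.T) * TRAIT_LN_SD
    traits = pd.DataFrame(
        np.exp(lnT), columns=[TRAIT_CSV_COLUMNS[t] for t in TRAITS]
    )
    traits.insert(0, "species_id", pool)

    plot_cont = [continents[p % 2] for p in range(cfg.n_plots)]
    membership: list[set] = []
    for p in range(cfg.n_plots):
        cont = plot_cont[p]
        natives = [s for s in pool if native_cont[s] == cont]
        r = 3 + rng.poisson(cfg.richness_mean)
        comm = set(rng.choice(natives, size=min(r, len(natives)), replace=False))
        for s in focal:
            prob = cfg.p_focal_native if native_cont[s] == cont else cfg.p_focal_alien
            if rng.random() < prob:
                comm.add(s)
        if rng.random() < cfg.p_alien_contaminant:
            aliens = [s for s in pool if native_cont[s] != cont and s not in focal]
            comm.add(str(rng.choice(aliens)))
        membership.append(comm)

    # guarantee each focal species its minimum plots per range
    for s in focal:
        for cont in continents:
            pids = [p for p in range(cfg.n_plots) if plot_cont[p] == cont]
            missing = [p for p in pids if s not in membership[p]]
            need = cfg.min_range_plots - (len(pids) - len(missing))
            if need > 0:
                extra = rng.choice(missing, size=min(need, len(missing)),
                                   replace=False)
                for p in extra:
                    membership[p].add(s)

    records = []
    climate_rows = []
    hii = {}
    for p in range(cfg.n_plots):
        pid = f"plot{p:04d}"
        cont = plot_cont[p]
        lat_lo, lat_hi = CONTINENTS[cont]
        lat = float(rng.uniform(lat_lo, lat_hi))
        lon = float(rng.uniform(-30, 30) + (0 if cont == "Eurasia" else -90))
        area = float(100.0 + rng.lognormal(np.log(250.0), 0.8))
        tcover = float(rng.uniform(25.0, 95.0))
        comm = sorted(membership[p])
        covers = _community_covers(len(comm), cfg.dirichlet_conc, rng)
        for s, c in zip(comm, covers):
            records.append(
                (pid, lat, lon, area, tcover, cont, s, float(c), True,
                 native_cont[s] != cont)
            )
        if rng.random() < cfg.p_herb_plot:
            for h in rng.choice(herbs, size=rng.integers(1, 3), replace=False):
                records.append(
                    (pid, lat, lon, area, tcover, cont, str(h),
                     float(rng.uniform(1.0, 30.0)), False, False)
                )
        hii[pid] = float(rng.uniform(0.0, 64.0))

        t_base = 28.0 - 0.45 * lat
        t_amp = 4.0 + 0.35 * lat
        p_base = float(rng.uniform(45.0, 110.0))
        for yr in range(cfg.n_years_climate):
            for mo in range(1, 13):
                t = t_base - t_amp * np.cos(2 * np.pi * (mo - 1) / 12.0) \
                    + rng.normal(0.0, 1.2)
                pmean = p_base * (1.0 + 0.4 * np.sin(2 * np.pi * mo / 12.0))
                prec = rng.gamma(2.0, pmean / 2.0)
                climate_rows.append((pid, lat, 1981 + yr, mo, float(t), float(prec)))

    plots = pd.DataFrame(
        records,
        columns=["plot_id", "latitude", "longitude", "area_m2",
                 "tree_layer_cover", "continent", "species_id", "cover",
                 "woody", "alien_here"],
    )
    climate = pd.DataFrame(
        climate_rows,
        columns=["plot_id", "latitude", "year", "month", "tmean_c", "prec_mm"],
    )
    return {
        "plots": plots,
        "traits": traits,
        "climate": climate,
        "hii": pd.Series(hii, name="hii"),
        "focal_species": focal,
        "native_continents": {s: frozenset([native_cont[s]]) for s in focal},
        "config": cfg,
    }


def gen_range_data(
    n_species: int = 20,
    n_plots: int = 200,
    range_effect: float = 0.0,
    species_per_plot: int = 2,
    base: float = 0.40,
    sigma_species: float = 0.05,
    sigma_plot: float = 0.04,
    sigma_resid: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate abundance rows for the native-vs-alien mixed model.

    Plots are split between two regions; each species is native to one
    region, so range (native/alien) arises from the species-region
    crossing. ``range_effect`` is the additive alien effect on the raw
    abundance scale (0 gives the null). Values are generated well inside
    (0, 1) so the Gaussian model applies.
    """
    rng = np.random.default_rng(seed)
    plot_region = rng.integers(0, 2, size=n_plots)
    species_region = rng.integers(0, 2, size=n_species)
    a_s = rng.normal(0.0, sigma_species, size=n_species)
    c_p = rng.normal(0.0, sigma_plot, size=n_plots)
    rows = []
    for p in range(n_plots):
        for s in rng.choice(n_species, size=species_per_plot, replace=False):
            alien = int(species_region[s] != plot_region[p])
            y = base + range_effect * alien + a_s[s] + c_p[p] \
                + rng.normal(0.0, sigma_resid)
            rows.append((f"sp{s:03d}", f"plot{p:04d}",
                         "alien" if alien else "native", float(np.clip(y, 1e-4, 1.0))))
    return pd.DataFrame(rows, columns=["focal_species", "plot_id", "range", "rel_abund"])
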
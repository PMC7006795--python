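"""Two-level hierarchical Bayesian regression of ln relative abundance.

Level 1 (observations, i = rows of the analysis table; j = focal
species, p = plot)::

    y_ij ~ Normal(alpha_j + sum_k beta_jk x_ik
                  + sum_{k in I} delta_k (x_ik * range_i) + u_p, sigma_resid^2)

with nine main-effect predictors K = {dissim, dSLA, dH, dSM, dWD, HII,
SPEI, range, richness}, seven global range-interaction coefficients
delta_k (no interaction for richness or range itself, and no
species-level variation in the interactions), and a plot random effect
u_p ~ Normal(0, sigma_plot^2).

Level 2 (slopes as outcomes; m indexes species traits SLA, H, SM, WD on
the standardized ln scale)::

    alpha_j  ~ Normal(gamma_int_0  + sum_m gamma_int_m  T_jm, sigma_int^2)
    beta_jk  ~ Normal(gamma_k_0    + sum_m gamma_k_m    T_jm, sigma_k^2)

so each species-specific intercept and slope is itself regressed on the
species' own traits, propagating slope uncertainty into the trait
effects.

Priors: every location parameter (gamma, delta) ~ Normal(0, 10^3);
every standard deviation ~ Uniform(0, 100).

Inference is a blocked Gibbs sampler: the model is conditionally
conjugate, with multivariate-normal full conditionals for the
(alpha_j, beta_j) blocks, the plot effects, the interaction block and
each level-2 regression, and truncated inverse-gamma full conditionals
for the variances implied by the uniform priors on the standard
deviations. Three chains of 10,000 retained iterations after 1,000
burn-in are the reference protocol; all counts are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

MAIN_EFFECTS = [
    "dissim",
    "d_sla",
    "d_height",
    "d_sm",
    "d_wd",
    "hii",
    "spei",
    "range",
    "richness",
]
INTERACTIONS = ["dissim", "d_sla", "d_height", "d_sm", "d_wd", "hii", "spei"]
L2_COVARIATES = ["sla", "height", "sm", "wd"]
EQUATIONS = ["intercept"] + MAIN_EFFECTS  # one level-2 regression per equation


class ModelError(ValueError):
    pass


@dataclass
class HierModelSpec:
    """Model structure and MCMC protocol."""

    main_effects: tuple = tuple(MAIN_EFFECTS)
    interactions: tuple = tuple(INTERACTIONS)
    l2_covariates: tuple = tuple(L2_COVARIATES)
    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 1_000
    prior_location_variance: float = 1_000.0
    prior_sigma_upper: float = 100.0
    store_latent: bool = False  # also keep species/plot effect draws

    def with_protocol(self, **kw) -> "HierModelSpec":
        return replace(self, **kw)


@dataclass
class ModelData:
    """Standardized inputs to the sampler.

    ``X`` holds the main-effect columns in ``MAIN_EFFECTS`` order
    (``range`` standardized like everything else); ``Z`` the
    interaction columns (x_k * range); ``T`` the (J, 4) species-trait
    matrix on the standardized ln scale.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    species_idx: np.ndarray
    plot_idx: np.ndarray
    T: np.ndarray
    species_ids: list = field(default_factory=list)
    plot_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return self.T.shape[0]

    @property
    def n_plots(self) -> int:
        return int(self.plot_idx.max()) + 1 if self.n else 0

    def validate(self) -> None:
        n = self.n
        if not (self.X.shape == (n, len(MAIN_EFFECTS)) and self.Z.shape[0] == n):
            raise ModelError("design matrix shapes inconsistent with y")
        if not np.isfinite(self.y).all() or not np.isfinite(self.X).all():
            raise ModelError("non-finite values in model data")


@dataclass
class StandardizationParams:
    """Column means/sds used for scaling; kept for back-transformation."""

    mean: dict
    sd: dict

    def transform(self, name: str, x):
        return (np.asarray(x, dtype=float) - self.mean[name]) / self.sd[name]

    def inverse(self, name: str, z):
        return np.asarray(z, dtype=float) * self.sd[name] + self.mean[name]


def standardize(rows: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Scale the analysis table: ln-transform the response, then centre and
    scale every variable (including the native/alien indicator) to mean 0,
    sd 1.

    Raises :class:`ModelError` naming any zero-variance predictor.
    """
    if len(rows) < 2:
        raise ModelError("need at least two analysis rows to standardize")
    out = rows.copy()
    out["y"] = np.log(out["rel_abund"].to_numpy(dtype=float))
    if out["range"].dtype == object:
        out["range"] = (out["range"] == "alien").astype(float)
    mean: dict = {}
    sd: dict = {}
    for col in ["y"] + MAIN_EFFECTS:
        v = out[col].to_numpy(dtype=float)
        m, s = v.mean(), v.std(ddof=0)
        if s < 1e-12:
            raise ModelError(f"zero-variance variable: {col!r}")
        mean[col], sd[col] = float(m), float(s)
        out[col] = (v - m) / s
    return out, StandardizationParams(mean, sd)


def build_model_data(
    rows_std: pd.DataFrame, species_lntraits: pd.DataFrame
) -> ModelData:
    """Assemble :class:`ModelData` from a standardized analysis table.

    ``species_lntraits`` holds the focal species' ln traits (columns
    sla/height/sm/wd, or the raw-trait CSV names handled by
    :func:`rangeabund.trait_metrics.log_trait_table`); they are
    standardized across the focal species here.
    """
    species_ids = sorted(rows_std["focal_species"].unique())
    plot_ids = sorted(rows_std["plot_id"].unique())
    smap = {s: i for i, s in enumerate(species_ids)}
    pmap = {p: i for i, p in enumerate(plot_ids)}
    T_raw = species_lntraits.loc[species_ids, L2_COVARIATES].to_numpy(dtype=float)
    sdv = T_raw.std(axis=0, ddof=0)
    if (sdv < 1e-12).any():
        raise ModelError("zero-variance species trait among focal species")
    T = (T_raw - T_raw.mean(axis=0)) / sdv
    X = rows_std[MAIN_EFFECTS].to_numpy(dtype=float)
    rng_col = rows_std["range"].to_numpy(dtype=float)
    Z = X[:, [MAIN_EFFECTS.index(k) for k in INTERACTIONS]] * rng_col[:, None]
    data = ModelData(
        y=rows_std["y"].to_numpy(dtype=float),
        X=X,
        Z=Z,
        species_idx=rows_std["focal_species"].map(smap).to_numpy(dtype=np.intp),
        plot_idx=rows_std["plot_id"].map(pmap).to_numpy(dtype=np.intp),
        T=T,
        species_ids=species_ids,
        plot_ids=plot_ids,
    )
    data.validate()
    return data


# ---------------------------------------------------------------------------
# joint log density (used by tests as the inferential target)
# ---------------------------------------------------------------------------

def model_logdensity(params: dict, data: ModelData, spec: HierModelSpec) -> float:
    """Log joint density of data and parameters under the model.

    ``params`` keys: ``gamma`` (10, 5), ``delta`` (7,), ``theta`` (J, 10)
    with column 0 the intercepts alpha_j, ``u`` (P,), ``sigma_theta``
    (10,), ``sigma_plot``, ``sigma_resid``. Returns ``-inf`` when any
    standard deviation leaves the (0, upper) prior support.
    """
    gamma = np.asarray(params["gamma"], dtype=float)
    delta = np.asarray(params["delta"], dtype=float)
    theta = np.asarray(params["theta"], dtype=float)
    u = np.asarray(params["u"], dtype=float)
    sig_t = np.asarray(params["sigma_theta"], dtype=float)
    sig_u = float(params["sigma_plot"])
    sig_e = float(params["sigma_resid"])

    upper = spec.prior_sigma_upper
    sigmas = np.concatenate([sig_t, [sig_u, sig_e]])
    if np.any(sigmas <= 0) or np.any(sigmas >= upper):
        return -np.inf

    W = np.column_stack([np.ones(data.n), data.X])
    mu_y = (
        np.einsum("ij,ij->i", W, theta[data.species_idx])
        + data.Z @ delta
        + u[data.plot_idx]
    )
    ld = stats.norm.logpdf(data.y, mu_y, sig_e).sum()
    U = np.column_stack([np.ones(data.n_species), data.T])
    mu_theta = U @ gamma.T  # (J, 10)
    ld += stats.norm.logpdf(theta, mu_theta, sig_t[None, :]).sum()
    ld += stats.norm.logpdf(u, 0.0, sig_u).sum()
    loc_sd = np.sqrt(spec.prior_location_variance)
    ld += stats.norm.logpdf(gamma, 0.0, loc_sd).sum()
    ld += stats.norm.logpdf(delta, 0.0, loc_sd).sum()
    ld += len(sigmas) * np.log(1.0 / upper)  # uniform prior on each sigma
    return float(ld)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def parameter_names(spec: HierModelSpec, data: ModelData) -> list[str]:
    names = [
        f"gamma_{eq}_{cov}"
        for eq in EQUATIONS
        for cov in ["0", *spec.l2_covariates]
    ]
    names += [f"delta_{k}" for k in spec.interactions]
    names += [f"sigma_{eq}" for eq in EQUATIONS]
    names += ["sigma_plot", "sigma_resid"]
    if spec.store_latent:
        names += [
            f"theta_{s}_{eq}" for s in data.species_ids for eq in EQUATIONS
        ]
        names += [f"u_{p}" for p in data.plot_ids]
    return names


@dataclass
class PosteriorDraws:
    """MCMC output: array indexed (chain, iteration, parameter)."""

    draws: np.ndarray
    names: list
    converged: bool | None = None

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.index(name)]

    def select(self, prefix: str) -> list[str]:
        return [n for n in self.names if n.startswith(prefix)]

    def to_frame(self) -> pd.DataFrame:
        m, n, p = self.draws.shape
        chain = np.repeat(np.arange(m), n * p)
        it = np.tile(np.repeat(np.arange(n), p), m)
        par = np.tile(np.array(self.names, dtype=object), m * n)
        return pd.DataFrame(
            {"chain": chain, "iteration": it, "parameter": par,
             "value": self.draws.reshape(-1)}
        )


def _sample_mvn_precision(A: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(A^-1 b, A^-1) for a batch of precision matrices (B, d, d)."""
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, b[..., None])[..., 0]
    z = rng.standard_normal(b.shape)
    noise = np.linalg.solve(np.swapaxes(L, -1, -2), z[..., None])[..., 0]
    return mean + noise


def _sample_trunc_invgamma(a, scale, upper_sq, rng):
    """Variance draws from InvGamma(a, scale) truncated to (0, upper_sq).

    When the truncation point sits far in the lower tail (CDF underflow),
    the conditional is approximated by its exponential tail at the
    boundary — mass is then concentrated within O(upper_sq^2/scale) of
    the cap, which the approximation reproduces.
    """
    a = np.asarray(a, dtype=float)
    scale = np.asarray(scale, dtype=float)
    fmax = stats.invgamma.cdf(upper_sq, a, scale=scale)
    u = rng.uniform(size=a.shape)
    with np.errstate(all="ignore"):
        v = stats.invgamma.ppf(u * fmax, a, scale=scale)
    bad = ~np.isfinite(v) | (v <= 0) | (fmax < 1e-290)
    if np.any(bad):
        rate = scale[bad] / upper_sq**2 - (a[bad] + 1.0) / upper_sq
        rate = np.clip(rate, 1e-12, None)
        e = rng.exponential(size=bad.sum()) / rate
        v_b = np.clip(upper_sq - e, 0.5 * upper_sq, upper_sq * (1 - 1e-12))
        v = np.where(bad, 0.0, np.nan_to_num(v, nan=0.0))
        v[bad] = v_b
    return v


def _run_chain(data: ModelData, spec: HierModelSpec, rng) -> np.ndarray:
    n, J, P = data.n, data.n_species, data.n_plots
    K = len(MAIN_EFFECTS)
    d = K + 1  # intercept + slopes per species
    q = len(spec.interactions)
    mL2 = len(spec.l2_covariates) + 1
    upper = spec.prior_sigma_upper
    prior_prec = 1.0 / spec.prior_location_variance

    W = np.column_stack([np.ones(n), data.X])
    Z = data.Z
    U = np.column_stack([np.ones(J), data.T])
    sp, pl = data.species_idx, data.plot_idx

    WtW = np.zeros((J, d, d))
    for j in range(J):
        Wj = W[sp == j]
        WtW[j] = Wj.T @ Wj
    ZtZ = Z.T @ Z
    UtU = U.T @ U
    n_p = np.bincount(pl, minlength=P).astype(float)
    n_j = np.bincount(sp, minlength=J).astype(float)
    if (n_j == 0).any():
        raise ModelError("species with no rows in model data")

    # overdispersed start
    sig_theta = rng.uniform(0.3, 1.5, size=d)
    sig_u = rng.uniform(0.3, 1.5)
    sig_e = rng.uniform(0.5, 1.5)
    theta = rng.normal(0.0, 0.3, size=(J, d))
    u = np.zeros(P)
    delta = np.zeros(q)
    gamma = np.zeros((d, mL2))

    total = spec.burn_in + spec.iterations
    n_par = d * mL2 + q + d + 2
    if spec.store_latent:
        n_par += J * d + P
    out = np.empty((spec.iterations, n_par))

    eyeq = np.eye(q)
    eyem = np.eye(mL2)
    ig_a = np.concatenate([np.full(d, (J - 1) / 2.0), [(P - 1) / 2.0, (n - 1) / 2.0]])

    for it in range(total):
        # --- species blocks (alpha_j, beta_j) jointly
        r = data.y - Z @ delta - u[pl]
        Wtr = np.empty((J, d))
        for c in range(d):
            Wtr[:, c] = np.bincount(sp, weights=W[:, c] * r, minlength=J)
        dinv = 1.0 / sig_theta**2
        A = WtW / sig_e**2 + np.diag(dinv)[None, :, :]
        mu_theta = U @ gamma.T  # (J, d)
        b = Wtr / sig_e**2 + mu_theta * dinv[None, :]
        theta = _sample_mvn_precision(A, b, rng)

        fitted_sp = np.einsum("ij,ij->i", W, theta[sp])

        # --- plot effects
        r = data.y - fitted_sp - Z @ delta
        s_p = np.bincount(pl, weights=r, minlength=P)
        prec = n_p / sig_e**2 + 1.0 / sig_u**2
        u = s_p / sig_e**2 / prec + rng.standard_normal(P) / np.sqrt(prec)

        # --- interaction block
        r = data.y - fitted_sp - u[pl]
        A1 = ZtZ / sig_e**2 + prior_prec * eyeq
        b1 = Z.T @ r / sig_e**2
        delta = _sample_mvn_precision(A1[None], b1[None], rng)[0]

        # --- level-2 regressions, one per equation
        A2 = UtU[None] / (sig_theta**2)[:, None, None] + prior_prec * eyem[None]
        b2 = (U.T @ theta).T / (sig_theta**2)[:, None]
        gamma = _sample_mvn_precision(A2, b2, rng)

        # --- variances
        mu_theta = U @ gamma.T
        ss_theta = ((theta - mu_theta) ** 2).sum(axis=0)
        resid = data.y - fitted_sp - Z @ delta - u[pl]
        ss = np.concatenate([ss_theta, [u @ u, resid @ resid]])
        v = _sample_trunc_invgamma(ig_a, ss / 2.0, upper**2, rng)
        sig_theta = np.sqrt(v[:d])
        sig_u = float(np.sqrt(v[d]))
        sig_e = float(np.sqrt(v[d + 1]))

        if it >= spec.burn_in:
            k = it - spec.burn_in
            vec = [gamma.reshape(-1), delta, sig_theta, [sig_u, sig_e]]
            if spec.store_latent:
                vec += [theta.reshape(-1), u]
            out[k] = np.concatenate([np.asarray(x, dtype=float) for x in vec])
    return out


def sample_posterior(
    data: ModelData, spec: HierModelSpec | None = None, seed: int = 0
) -> PosteriorDraws:
    """Run the blocked Gibbs sampler; returns draws for the level-2
    coefficients, interaction coefficients and standard deviations (plus
    species/plot effects when ``spec.store_latent``).

    Chains are seeded independently from ``seed``; reruns with the same
    seed and spec are bit-for-bit reproducible.
    """
    spec = spec or HierModelSpec()
    data.validate()
    seqs = np.random.SeedSequence(seed).spawn(spec.chains)
    chains = [
        _run_chain(data, spec, np.random.Generator(np.random.PCG64(s)))
        for s in seqs
    ]
    draws = np.stack(chains, axis=0)
    pd_ = PosteriorDraws(draws=draws, names=parameter_names(spec, data))
    try:
        psrf, mpsrf = gelman_rubin(pd_.draws)
        pd_.converged = bool(np.nanmax(psrf) <= 1.1 and mpsrf <= 1.1)
    except Exception:  # diagnostics never block returning draws
        pd_.converged = None
    return pd_


# ---------------------------------------------------------------------------
# diagnostics & summaries
# ---------------------------------------------------------------------------

def gelman_rubin(draws: np.ndarray) -> tuple[np.ndarray, float]:
    """Potential scale reduction factors from (chains, iterations, params).

    Univariate: ``Rhat = sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the
    mean within-chain variance and ``B/n`` the between-chain variance of
    chain means. Multivariate: ``sqrt((n-1)/n + lambda_1 / n)`` with
    ``lambda_1`` the largest eigenvalue of ``W^-1 B``.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    m, n, p = draws.shape
    if m < 2:
        raise ModelError("Gelman-Rubin diagnostic needs at least two chains")
    chain_means = draws.mean(axis=1)  # (m, p)
    W_diag = draws.var(axis=1, ddof=1).mean(axis=0)  # (p,)
    B_diag = n * chain_means.var(axis=0, ddof=1)  # (p,)
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(((n - 1) / n * W_diag + B_diag / n) / W_diag)

    centred = draws - chain_means[:, None, :]
    W = np.einsum("mip,miq->pq", centred, centred) / (m * (n - 1))
    dm = chain_means - chain_means.mean(axis=0)
    B = n * np.einsum("mp,mq->pq", dm, dm) / (m - 1)
    W = W + 1e-12 * np.eye(p)
    from scipy.linalg import eigh

    lam1 = eigh(B, W, eigvals_only=True, subset_by_index=(p - 1, p - 1))[0]
    mpsrf = float(np.sqrt((n - 1) / n + lam1 / n))
    return psrf, mpsrf


def vif(X: np.ndarray | pd.DataFrame) -> pd.Series:
    """Variance inflation factors, 1 / (1 - R^2_k), of each column of ``X``
    regressed (with intercept) on the remaining columns.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"x{k}" for k in range(M.shape[1])]
    n, k = M.shape
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), M])) < k + 1:
        raise ModelError("rank-deficient design; VIF undefined")
    out = []
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        yj = M[:, j]
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss
        if 1.0 - r2 < 1e-12:
            raise ModelError(f"predictor {names[j]!r} perfectly collinear")
        out.append(1.0 / (1.0 - r2))
    return pd.Series(out, index=names, name="vif")


def summarize_effects(draws: PosteriorDraws, names: list[str] | None = None) -> pd.DataFrame:
    """Posterior median and central 95% credible interval per parameter.

    ``significant`` flags intervals excluding zero (reporting convention
    only; no decision theory implied).
    """
    names = names or draws.names
    rows = []
    for nm in names:
        v = draws.get(nm).reshape(-1)
        lo, med, hi = np.quantile(v, [0.025, 0.5, 0.975])
        rows.append((nm, med, lo, hi, bool(lo > 0 or hi < 0)))
    return pd.DataFrame(
        rows, columns=["parameter", "median", "q2.5", "q97.5", "significant"]
    ).set_index("parameter")


def range_effect_panels(
    draws: PosteriorDraws, r_native_std: float, r_alien_std: float
) -> pd.DataFrame:
    """Per-range effect summaries composed from the posterior draws.

    For predictors with a range interaction, the effect in range g is
    ``gamma_k_0 + delta_k * r_g`` with ``r_g`` the standardized value of
    the native/alien indicator in that range; richness and range itself
    have no interaction, so both columns show the main effect.
    """
    rows = []
    for k in MAIN_EFFECTS:
        g = draws.get(f"gamma_{k}_0").reshape(-1)
        if k in INTERACTIONS:
            d = draws.get(f"delta_{k}").reshape(-1)
            panels = {"native": g + d * r_native_std, "alien": g + d * r_alien_std}
        else:
            panels = {"native": g, "alien": g}
        for rng_name, v in panels.items():
            lo, med, hi = np.quantile(v, [0.025, 0.5, 0.975])
            rows.append((f"effect_{k}_{rng_name}", med, lo, hi,
                         bool(lo > 0 or hi < 0)))
    return pd.DataFrame(
        rows, columns=["parameter", "median", "q2.5", "q97.5", "significant"]
    ).set_index("parameter")


def bayes_r2(draws: PosteriorDraws, data: ModelData, spec: HierModelSpec,
             n_draws: int = 200, seed: int = 0) -> float:
    """Bayesian R^2: posterior mean of var(fit)/(var(fit)+sigma_resid^2).

    Uses the level-2 conditional means for the species effects, i.e. the
    variance explained by predictors, traits, and plot effects, from a
    thinned subsample of draws.
    """
    rng = np.random.default_rng(seed)
    m, n_it, _ = draws.draws.shape
    W = np.column_stack([np.ones(data.n), data.X])
    U = np.column_stack([np.ones(data.n_species), data.T])
    gamma_names = [n for n in draws.names if n.startswith("gamma_")]
    gidx = [draws.index(n) for n in gamma_names]
    didx = [draws.index(n) for n in draws.select("delta_")]
    sidx = draws.index("sigma_resid")
    r2 = []
    for _ in range(n_draws):
        c = rng.integers(m)
        t = rng.integers(n_it)
        gamma = draws.draws[c, t, gidx].reshape(len(EQUATIONS), -1)
        delta = draws.draws[c, t, didx]
        mu_theta = U @ gamma.T
        fit = np.einsum("ij,ij->i", W, mu_theta[data.species_idx]) + data.Z @ delta
        ve = fit.var()
        r2.append(ve / (ve + draws.draws[c, t, sidx] ** 2))
    return float(np.mean(r2))
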
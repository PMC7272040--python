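"""Among-habitat comparison models and the covariate-selection workflow.

Two kinds of hierarchical Bayesian models are provided, both with a site
random intercept:

* habitat-contrast models, ``metric ~ habitat + (1 | site)``, one observation
  family per response type (Gaussian for rugosity/verticality/field-of-view,
  beta regression for proportions, negative binomial for counts, Gamma for
  biomass), summarised as back-transformed per-habitat means with 95%
  highest-posterior-density intervals (HPDI) and all pairwise contrasts; and
* fish-distribution models, ``abundance|biomass ~ covariates + (1 | site)``
  with a Gamma family and log link, reporting the posterior probability that
  each slope is positive.

The covariate-selection workflow screens the structural metrics for
collinearity (|Pearson r| > 0.7 groups), collapses each collinear group to
its first principal component, and chooses among candidate covariate sets by
exact leave-one-out cross-validation (refitting without each unit in turn,
feasible at the 15-unit scale of a 3-site x 5-habitat design).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import FAMILIES, GLMM, MCMCConfig, run_mcmc

HABITAT_ORDER = ["slope", "crest", "outer_flat", "mid_flat", "inner_flat"]

_FAMILY_ALIASES = {
    "gaussian": "gaussian",
    "gaussian-identity": "gaussian",
    "beta": "beta",
    "beta-binomial-logit": "beta",
    "negbin": "negbin",
    "negative-binomial-log": "negbin",
    "gamma": "gamma",
    "gamma-log": "gamma",
}


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one hierarchical model.

    ``fixed = ["habitat"]`` requests a categorical cell-means habitat model;
    any other list is treated as continuous covariates (standardized
    internally for fitting, slopes reported on the original scale).
    """

    response: str
    family: str
    fixed: tuple = ("habitat",)
    group: str = "site"
    name: str = ""

    def __post_init__(self):
        if self.family not in _FAMILY_ALIASES:
            raise ValueError(f"unknown family '{self.family}'")
        object.__setattr__(self, "fixed", tuple(self.fixed))
        if not self.name:
            object.__setattr__(self, "name", f"{self.response}~{'+'.join(self.fixed)}")

    @property
    def engine_family(self) -> str:
        return _FAMILY_ALIASES[self.family]

    @property
    def is_categorical(self) -> bool:
        return self.fixed == ("habitat",)


def add_offset(proportions, c: float = 0.001):
    """Shift proportions off the boundaries of [0, 1] for beta-family fits.

    Every value gains the small constant ``c`` (accounting for exact zeros);
    values that reach 1 after the shift are compressed by
    ``y <- (y * (n - 1) + 0.5) / n`` with ``n`` the sample size, keeping the
    support strictly inside (0, 1). Interior values are left untouched
    beyond the additive shift.
    """
    y = np.asarray(proportions, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = y + c
    n = max(2, y.size)
    hi = out >= 1.0
    out[hi] = (out[hi] * (n - 1) + 0.5) / n
    return out


def hpdi(draws, prob: float = 0.95) -> tuple:
    """Shortest contiguous interval containing ``ceil(prob * n)`` sorted draws."""
    a = np.sort(np.asarray(draws, dtype=float).ravel())
    n = a.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HPDI")
    m = int(math.ceil(prob * n))
    if m >= n:
        return (float(a[0]), float(a[-1]))
    widths = a[m - 1 :] - a[: n - m + 1]
    i = int(np.argmin(widths))
    return (float(a[i]), float(a[i + m - 1]))


# ---------------------------------------------------------------------------
# model construction


def _build_glmm(spec: ModelSpec, data: pd.DataFrame):
    """Returns (GLMM, transform-info dict)."""
    y = data[spec.response].to_numpy(dtype=float)
    sites = pd.unique(data[spec.group])
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for the random intercept")
    site_idx = pd.Categorical(data[spec.group], categories=sites).codes.astype(int)
    fam = spec.engine_family
    info = {"family": fam}

    if fam == "gaussian":
        m, s = float(np.mean(y)), float(np.std(y))
        s = s if s > 0 else 1.0
        info["y_center"], info["y_scale"] = m, s
        y_fit = (y - m) / s
    else:
        info["y_center"], info["y_scale"] = 0.0, 1.0
        y_fit = y

    if spec.is_categorical:
        levels = [h for h in HABITAT_ORDER if h in set(data["habitat"])]
        levels += sorted(set(data["habitat"]) - set(levels))
        codes = pd.Categorical(data["habitat"], categories=levels).codes
        X = np.eye(len(levels))[codes]
        coef_names = list(levels)
        prior_scale = np.full(len(levels), 5.0)
        prior_loc = np.zeros(len(levels))
        info["levels"] = levels
    else:
        cols = list(spec.fixed)
        xs = data[cols].to_numpy(dtype=float)
        mu = xs.mean(axis=0)
        sd = xs.std(axis=0)
        if np.any(sd == 0):
            bad = [c for c, s_ in zip(cols, sd) if s_ == 0]
            raise ValueError(f"constant covariate(s): {bad}")
        X = np.column_stack([np.ones(len(data)), (xs - mu) / sd])
        coef_names = ["intercept"] + cols
        prior_scale = np.concatenate([[5.0], np.full(len(cols), 2.5)])
        prior_loc = np.zeros(len(cols) + 1)
        info["x_center"], info["x_scale"] = mu, sd
    model = GLMM(
        y=y_fit,
        X=X,
        group_idx=site_idx,
        family=fam,
        coef_names=coef_names,
        group_names=list(sites),
        prior_scale_beta=prior_scale,
        prior_loc_beta=prior_loc,
    )
    return model, info


@dataclass
class PosteriorSummary:
    """Posterior draws and diagnostics for one fitted model."""

    spec: ModelSpec
    coef_names: list
    draws_link: np.ndarray       # (n_draws, p) on the (standardized) link scale
    level_draws: np.ndarray | None  # back-transformed per-habitat means (categorical)
    slope_draws: dict            # original-scale slope draws (continuous models)
    rhat: dict
    ess: dict
    seed: int
    mcmc: MCMCConfig
    transform: dict = field(default_factory=dict)

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        if self.level_draws is not None:
            for j, name in enumerate(self.coef_names):
                d = self.level_draws[:, j]
                lo, hi = hpdi(d, prob)
                rows.append(
                    {"level": name, "mean": float(d.mean()), "hpdi_lower": lo,
                     "hpdi_upper": hi, "rhat": self.rhat[name], "ess": self.ess[name]}
                )
        else:
            for name in self.coef_names:
                d = self.slope_draws.get(name, None)
                if d is None:
                    continue
                lo, hi = hpdi(d, prob)
                rows.append(
                    {"level": name, "mean": float(d.mean()), "hpdi_lower": lo,
                     "hpdi_upper": hi, "rhat": self.rhat[name], "ess": self.ess[name],
                     "p_positive": float(np.mean(d > 0))}
                )
        return pd.DataFrame(rows)

    def p_positive(self, covariate: str) -> float:
        """Posterior probability that a covariate's slope is positive."""
        return float(np.mean(self.slope_draws[covariate] > 0))

    def predict(self, new_data: pd.DataFrame, prob: float = 0.95) -> pd.DataFrame:
        """Population-level predicted mean with an HPDI band (continuous models)."""
        if self.level_draws is not None:
            raise ValueError("predict() applies to continuous-covariate models")
        cols = list(self.spec.fixed)
        xs = new_data[cols].to_numpy(dtype=float)
        Xs = np.column_stack(
            [np.ones(len(new_data)), (xs - self.transform["x_center"]) / self.transform["x_scale"]]
        )
        eta = self.draws_link @ Xs.T
        mu = FAMILIES[self.spec.engine_family][1](eta)
        mu = mu * self.transform["y_scale"] + self.transform["y_center"]
        out = pd.DataFrame({c: new_data[c].to_numpy() for c in cols})
        out["mean"] = mu.mean(axis=0)
        bands = np.array([hpdi(mu[:, i], prob) for i in range(mu.shape[1])])
        out["hpdi_lower"], out["hpdi_upper"] = bands[:, 0], bands[:, 1]
        return out


def fit_habitat_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Fit one hierarchical model by MCMC and summarise its posterior.

    Raises :class:`reefscape.errors.ConvergenceError` (carrying the rhat
    table) if any parameter's rhat exceeds the configured threshold, and
    ``ValueError`` on a family/support mismatch.
    """
    mcmc = mcmc or MCMCConfig()
    model, info = _build_glmm(spec, data)
    draws, rhat, ess = run_mcmc(model, seed=seed, config=mcmc)
    p = model.n_coef
    beta = draws[:, :p]
    inv_link = FAMILIES[spec.engine_family][1]
    all_names = (
        model.coef_names
        + [f"u[{g}]" for g in model.group_names]
        + ["sigma_site", "aux"]
    )
    rhat_d = dict(zip(all_names, rhat))
    ess_d = dict(zip(all_names, ess))

    if spec.is_categorical:
        level_draws = inv_link(beta) * info["y_scale"] + info["y_center"]
        slope_draws = {}
    else:
        level_draws = None
        slope_draws = {}
        for j, cov in enumerate(spec.fixed, start=1):
            # slope per original covariate unit, on the link scale (undoing
            # the response standardization used for gaussian fits)
            slope_draws[cov] = beta[:, j] / info["x_scale"][j - 1] * info["y_scale"]
        slope_draws["intercept"] = (
            beta[:, 0] - (beta[:, 1:] * (info["x_center"] / info["x_scale"])).sum(axis=1)
        ) * info["y_scale"] + info["y_center"]
    return PosteriorSummary(
        spec=spec,
        coef_names=model.coef_names,
        draws_link=beta,
        level_draws=level_draws,
        slope_draws=slope_draws,
        rhat=rhat_d,
        ess=ess_d,
        seed=seed,
        mcmc=mcmc,
        transform=info,
    )


def pairwise_contrasts(level_draws, levels=None, prob: float = 0.95) -> pd.DataFrame:
    """All pairwise differences between level posteriors, with inference flags.

    ``level_draws`` is a (n_draws, L) array (e.g. ``PosteriorSummary.level_draws``)
    or a mapping level -> draws. A pair is flagged (``effect = True``) when
    the HPDI of its difference excludes zero; ``p_sign`` is the posterior
    probability of the difference's dominant sign.
    """
    if isinstance(level_draws, dict):
        levels = list(level_draws)
        mat = np.column_stack([level_draws[k] for k in levels])
    else:
        mat = np.asarray(level_draws, dtype=float)
        if levels is None:
            levels = [f"level_{i}" for i in range(mat.shape[1])]
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 levels for contrasts")
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            d = mat[:, i] - mat[:, j]
            lo, hi = hpdi(d, prob)
            p_pos = float(np.mean(d > 0))
            rows.append(
                {
                    "pair": f"{levels[i]} - {levels[j]}",
                    "mean_diff": float(d.mean()),
                    "hpdi_lower": lo,
                    "hpdi_upper": hi,
                    "p_sign": max(p_pos, 1.0 - p_pos),
                    "effect": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate selection


@dataclass(frozen=True)
class CollinearityResult:
    correlation: pd.DataFrame
    groups: list
    excluded: list


def collinearity_screen(covariates: pd.DataFrame, threshold: float = 0.7) -> CollinearityResult:
    """Pearson correlations and connected groups of distinctly collinear covariates.

    Covariates with |r| above ``threshold`` are linked; connected components
    with at least two members are reported as collinear groups. Zero-variance
    columns are excluded with a warning.
    """
    if len(covariates) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    excluded = [c for c in covariates.columns if covariates[c].std() == 0]
    if excluded:
        warnings.warn(f"zero-variance covariate(s) excluded from screen: {excluded}")
    use = covariates.drop(columns=excluded)
    corr = use.corr(method="pearson")
    cols = list(use.columns)
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if abs(corr.loc[a, b]) > threshold:
                parent[find(a)] = find(b)
    comp = {}
    for c in cols:
        comp.setdefault(find(c), []).append(c)
    groups = [sorted(g) for g in comp.values() if len(g) > 1]
    groups.sort(key=lambda g: (-len(g), g))
    return CollinearityResult(correlation=corr, groups=groups, excluded=excluded)


@dataclass(frozen=True)
class PC1Composite:
    scores: pd.Series
    loadings: pd.Series
    explained_variance_ratio: float


def pc1_composite(columns: pd.DataFrame, anchor: str | None = None) -> PC1Composite:
    """First-principal-component scores of a collinear metric group.

    Columns are centred and scaled to unit variance; the PC1 sign is fixed so
    the ``anchor`` column (rugosity when present) loads positively, making
    higher scores mean structurally more complex. Constant columns are
    excluded with a warning.
    """
    from sklearn.decomposition import PCA

    const = [c for c in columns.columns if columns[c].std() == 0]
    if const:
        warnings.warn(f"constant column(s) excluded from PC1: {const}")
    use = columns.drop(columns=const)
    if use.shape[1] < 2:
        raise ValueError("need at least 2 non-constant columns for a composite")
    Z = (use - use.mean()) / use.std(ddof=0)
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z.to_numpy())[:, 0]
    loadings = pca.components_[0]
    if anchor is None:
        anchor = "rugosity" if "rugosity" in use.columns else use.columns[0]
    sign = 1.0 if loadings[list(use.columns).index(anchor)] >= 0 else -1.0
    return PC1Composite(
        scores=pd.Series(sign * scores, index=columns.index, name="complexity_pc1"),
        loadings=pd.Series(sign * loadings, index=use.columns, name="pc1_loading"),
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
    )


@dataclass(frozen=True)
class LOOResult:
    table: pd.DataFrame
    best: ModelSpec


def loo_select(
    candidates: list,
    data: pd.DataFrame,
    seed: int = 0,
    n_laplace_draws: int = 200,
) -> LOOResult:
    """Rank candidate models by exact leave-one-out cross-validation.

    For each candidate and each observation, the model is refit on the
    remaining data (Laplace approximation of the refit posterior) and the
    left-out observation's log predictive density is averaged over posterior
    draws; the candidate's score is the sum over observations (elpd). Ties
    within numerical noise break toward fewer covariates. Candidates whose
    refits fail are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in candidates:
        try:
            elpd = _elpd_exact_loo(spec, data, rng, n_laplace_draws)
        except Exception as exc:  # noqa: BLE001 - candidate-level containment
            warnings.warn(f"candidate '{spec.name}' excluded from LOO ranking: {exc}")
            continue
        rows.append({"model": spec.name, "n_covariates": len(spec.fixed), "elpd_loo": elpd, "spec": spec})
    if not rows:
        raise ValueError("no candidate model could be scored")
    tbl = pd.DataFrame(rows).sort_values(
        ["elpd_loo", "n_covariates"], ascending=[False, True], kind="mergesort"
    )
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    best = tbl.iloc[0]["spec"]
    out_tbl = tbl.drop(columns="spec").reset_index(drop=True)
    return LOOResult(table=out_tbl, best=best)


def _elpd_exact_loo(spec: ModelSpec, data: pd.DataFrame, rng, n_draws: int) -> float:
    full_model, info = _build_glmm(spec, data)
    loglik_fn, inv_link, _ = FAMILIES[spec.engine_family]
    n = len(data)
    # warm-start every leave-one-out refit at the full-data mode: dropping one
    # of n observations barely moves the posterior, so a single local
    # optimisation from there suffices
    full_mode = full_model.map_fit(seed=int(rng.integers(0, 2**31 - 1)))
    elpd = 0.0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = GLMM(
            y=full_model.y[keep],
            X=full_model.X[keep],
            group_idx=full_model.group_idx[keep],
            family=full_model.family,
            coef_names=full_model.coef_names,
            group_names=full_model.group_names,
            prior_scale_beta=full_model.prior_scale_beta,
            prior_loc_beta=full_model.prior_loc_beta,
        )
        mode, cov = sub.laplace_fit(
            seed=int(rng.integers(0, 2**31 - 1)), x0=full_mode, n_restarts=0
        )
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        theta = mode + (rng.standard_normal((n_draws, mode.size)) * np.sqrt(w)) @ V.T
        beta = theta[:, : sub.n_coef]
        u = theta[:, sub.n_coef : sub.n_coef + sub.n_group]
        eta_i = beta @ full_model.X[i] + u[:, full_model.group_idx[i]]
        mu_i = inv_link(eta_i)
        if spec.engine_family == "beta":
            mu_i = np.clip(mu_i, 1e-9, 1 - 1e-9)
        aux = np.exp(np.clip(theta[:, -1], -15, 10))
        with np.errstate(all="ignore"):
            ll = loglik_fn(full_model.y[i], mu_i, aux)
        ll = ll[np.isfinite(ll)]
        if ll.size == 0:
            raise ValueError("left-out predictive density degenerate")
        # log mean exp over posterior draws
        m = float(np.max(ll))
        elpd += m + math.log(float(np.mean(np.exp(ll - m))))
    return elpd


def fit_fish_model(
    response: str,
    covariates,
    data: pd.DataFrame,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Gamma log-link hierarchical model of fish abundance or biomass.

    ``response`` names a strictly positive column of per-unit means;
    ``covariates`` the continuous predictors (e.g. grazing area, the
    complexity composite, depth). The returned summary reports slope HPDIs
    and the posterior probability each slope is positive; use
    :meth:`PosteriorSummary.predict` for the fitted curve with its HPDI band.
    """
    if np.any(data[response].to_numpy(dtype=float) <= 0):
        raise ValueError("fish model responses must be strictly positive")
    spec = ModelSpec(response=response, family="gamma-log", fixed=tuple(covariates))
    return fit_habitat_model(spec, data, seed=seed, mcmc=mcmc)
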
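import numpy as np
import pandas as pd
import pytest

from reefscape.errors import ConvergenceError
from reefscape.models import (
    ModelSpec,
    add_offset,
    collinearity_screen,
    fit_fish_model,
    fit_habitat_model,
    hpdi,
    loo_select,
    pairwise_contrasts,
    pc1_composite,
)
from reefscape.bayes import MCMCConfig


# ---------------------------------------------------------------------------
# add_offset


def test_add_offset_shifts_zero():
    out = add_offset(np.array([0.0, 0.573, 0.2]))
    assert out[0] == pytest.approx(0.001, abs=1e-12)
    assert out[1] == pytest.approx(0.574, abs=1e-12)
    assert out[2] == pytest.approx(0.201, abs=1e-12)


def test_add_offset_compresses_upper_boundary():
    y = np.array([1.0, 0.5, 0.25, 0.9])
    out = add_offset(y)
    n = y.size
    assert out[0] == pytest.approx((1.001 * (n - 1) + 0.5) / n, abs=1e-12)
    assert np.all(out > 0) and np.all(out < 1)


def test_add_offset_rejects_out_of_range():
    with pytest.raises(ValueError):
        add_offset(np.array([0.5, 1.2]))
    with pytest.raises(ValueError):
        add_offset(np.array([-0.1]))


# ---------------------------------------------------------------------------
# hpdi


def _hpdi_bruteforce(draws, prob):
    a = np.sort(draws)
    n = a.size
    m = int(np.ceil(prob * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        w = a[i + m - 1] - a[i]
        if w < best[0]:
            best = (w, (a[i], a[i + m - 1]))
    return best[1]


def test_hpdi_matches_bruteforce():
    rng = np.random.default_rng(17)
    for _ in range(10):
        draws = rng.gamma(2.0, 1.0, size=rng.integers(100, 400))
        for prob in (0.5, 0.9, 0.95):
            lo, hi = hpdi(draws, prob)
            blo, bhi = _hpdi_bruteforce(draws, prob)
            assert lo == pytest.approx(blo, abs=1e-12)
            assert hi == pytest.approx(bhi, abs=1e-12)


def test_hpdi_standard_normal():
    rng = np.random.default_rng(5)
    lo, hi = hpdi(rng.standard_normal(100_000), 0.95)
    assert lo == pytest.approx(-1.96, abs=0.04)
    assert hi == pytest.approx(1.96, abs=0.04)


def test_hpdi_shorter_than_central_for_skewed():
    rng = np.random.default_rng(7)
    draws = rng.lognormal(0.0, 1.0, size=50_000)
    lo, hi = hpdi(draws, 0.95)
    clo, chi = np.quantile(draws, [0.025, 0.975])
    assert hi - lo <= chi - clo + 1e-9


def test_hpdi_requires_enough_draws():
    with pytest.raises(ValueError):
        hpdi(np.zeros(99))


# ---------------------------------------------------------------------------
# pairwise contrasts


def test_contrasts_identical_levels_no_effect():
    rng = np.random.default_rng(1)
    d = rng.standard_normal(2000)
    tbl = pairwise_contrasts(np.column_stack([d, d + rng.normal(0, 1e-6, 2000)]), ["a", "b"])
    assert len(tbl) == 1
    assert not tbl.loc[0, "effect"]
    assert abs(tbl.loc[0, "mean_diff"]) < 1e-3


def test_contrasts_separated_levels_flagged():
    rng = np.random.default_rng(2)
    mat = np.column_stack(
        [rng.normal(0, 1, 2000), rng.normal(5, 1, 2000), rng.normal(5.1, 1, 2000)]
    )
    tbl = pairwise_contrasts(mat, ["lo", "hi1", "hi2"])
    assert len(tbl) == 3
    row = tbl[tbl["pair"] == "lo - hi1"].iloc[0]
    assert row["effect"] and row["mean_diff"] < 0 and row["p_sign"] > 0.99
    row2 = tbl[tbl["pair"] == "hi1 - hi2"].iloc[0]
    assert not row2["effect"]


def test_contrasts_accepts_dict_and_validates():
    rng = np.random.default_rng(3)
    d = {"a": rng.normal(0, 1, 500), "b": rng.normal(3, 1, 500)}
    tbl = pairwise_contrasts(d)
    assert tbl.loc[0, "pair"] == "a - b"
    with pytest.raises(ValueError):
        pairwise_contrasts(np.zeros((500, 1)), ["only"])


# ---------------------------------------------------------------------------
# collinearity screen and composite


def _metric_frame(n=15, seed=0):
    rng = np.random.default_rng(seed)
    latent = rng.normal(0, 1, n)
    return pd.DataFrame(
        {
            "rugosity": 1.5 + 0.3 * latent + rng.normal(0, 0.03, n),
            "verticality": 0.2 + 0.1 * latent + rng.normal(0, 0.01, n),
            "refuge_count": np.round(5 + 2 * latent + rng.normal(0, 0.2, n)),
            "depth": rng.normal(3, 1, n),
        }
    )


def test_screen_finds_latent_group():
    res = collinearity_screen(_metric_frame())
    assert res.groups == [["refuge_count", "rugosity", "verticality"]]
    assert res.excluded == []
    assert res.correlation.loc["rugosity", "verticality"] > 0.7


def test_screen_orthogonal_covariates_no_groups():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.standard_normal((200, 3)), columns=["a", "b", "c"])
    assert collinearity_screen(df).groups == []


def test_screen_excludes_constant_with_warning():
    df = _metric_frame()
    df["flat"] = 1.0
    with pytest.warns(UserWarning):
        res = collinearity_screen(df)
    assert res.excluded == ["flat"]
    assert "flat" not in res.correlation.columns


def test_screen_needs_three_rows():
    with pytest.raises(ValueError):
        collinearity_screen(_metric_frame().head(2))


def test_pc1_identical_columns_explains_everything():
    rng = np.random.default_rng(4)
    v = rng.normal(0, 1, 30)
    df = pd.DataFrame({"rugosity": v, "verticality": 2 * v + 1})
    comp = pc1_composite(df)
    assert comp.explained_variance_ratio == pytest.approx(1.0, abs=1e-9)
    assert np.corrcoef(comp.scores, v)[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_pc1_tracks_latent_and_anchors_on_rugosity():
    df = _metric_frame()[["rugosity", "verticality", "refuge_count"]]
    comp = pc1_composite(df)
    assert comp.loadings["rugosity"] > 0
    assert np.corrcoef(comp.scores, df["rugosity"])[0, 1] > 0.9
    assert comp.scores.mean() == pytest.approx(0.0, abs=1e-9)
    assert comp.scores.name == "complexity_pc1"


def test_pc1_excludes_constant_and_needs_two_columns():
    df = _metric_frame()[["rugosity", "verticality"]].copy()
    df["flat"] = 3.0
    with pytest.warns(UserWarning):
        comp = pc1_composite(df)
    assert "flat" not in comp.loadings.index
    with pytest.raises(ValueError):
        pc1_composite(pd.DataFrame({"rugosity": df["rugosity"], "flat": 1.0}))


# ---------------------------------------------------------------------------
# model declaration and validation


def test_modelspec_validation_and_name():
    spec = ModelSpec(response="rugosity", family="gaussian-identity")
    assert spec.is_categorical and spec.engine_family == "gaussian"
    assert spec.name == "rugosity~habitat"
    with pytest.raises(ValueError):
        ModelSpec(response="x", family="poisson")


def _habitat_data(seed=0, means=(2.0, 5.0, 8.0, 3.0, 1.0), sigma=0.3, n_rep=3):
    rng = np.random.default_rng(seed)
    habs = ["slope", "crest", "outer_flat", "mid_flat", "inner_flat"]
    site_eff = {"A": -0.2, "B": 0.0, "C": 0.2}
    rows = []
    for site, se in site_eff.items():
        for h, m in zip(habs, means):
            for _ in range(n_rep):
                rows.append({"site": site, "habitat": h, "y": m + se + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


def test_fit_requires_two_sites():
    df = _habitat_data().query("site == 'A'")
    with pytest.raises(ValueError):
        fit_habitat_model(ModelSpec(response="y", family="gaussian"), df)


def test_beta_family_rejects_unbounded_response():
    df = _habitat_data()  # y far outside (0, 1)
    with pytest.raises(ValueError):
        fit_habitat_model(ModelSpec(response="y", family="beta-binomial-logit"), df)


def test_constant_covariate_rejected():
    df = _habitat_data()
    df["flat"] = 2.0
    spec = ModelSpec(response="y", family="gaussian", fixed=("flat",))
    with pytest.raises(ValueError):
        fit_habitat_model(spec, df)


def test_fish_model_rejects_nonpositive_response():
    df = pd.DataFrame({"site": ["A", "B"], "y": [1.0, 0.0], "x": [0.1, 0.2]})
    with pytest.raises(ValueError):
        fit_fish_model("y", ["x"], df)


def test_nonconvergent_run_raises_with_rhat():
    df = _habitat_data()
    cfg = MCMCConfig(steps=60, thin=1, rhat_max=1.000001)
    with pytest.raises(ConvergenceError) as err:
        fit_habitat_model(ModelSpec(response="y", family="gaussian"), df, seed=0, mcmc=cfg)
    assert getattr(err.value, "rhat", None) is not None


# ---------------------------------------------------------------------------
# posterior recovery (full MCMC; kept small)


def test_habitat_model_recovers_cell_means():
    means = (2.0, 5.0, 8.0, 3.0, 1.0)
    df = _habitat_data(seed=42, means=means)
    fit = fit_habitat_model(ModelSpec(response="y", family="gaussian"), df, seed=1)
    summ = fit.summary()
    assert list(summ["level"]) == ["slope", "crest", "outer_flat", "mid_flat", "inner_flat"]
    for m, (_, row) in zip(means, summ.iterrows()):
        assert row["hpdi_lower"] - 0.3 < m < row["hpdi_upper"] + 0.3
        assert row["mean"] == pytest.approx(m, abs=0.4)
        assert row["rhat"] < 1.01
    tbl = pairwise_contrasts(fit.level_draws, summ["level"].tolist())
    big = tbl[tbl["pair"] == "crest - inner_flat"].iloc[0]
    assert big["effect"] and big["mean_diff"] == pytest.approx(4.0, abs=0.6)


def test_continuous_model_recovers_slope_and_predicts():
    rng = np.random.default_rng(8)
    n = 60
    x = rng.uniform(0, 2, n)
    site = np.repeat(["A", "B", "C"], n // 3)
    y = 1.0 + 2.0 * x + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"site": site, "x": x, "y": y})
    spec = ModelSpec(response="y", family="gaussian", fixed=("x",))
    fit = fit_habitat_model(spec, df, seed=2)
    lo, hi = hpdi(fit.slope_draws["x"])
    assert lo < 2.0 < hi
    ilo, ihi = hpdi(fit.slope_draws["intercept"])
    assert ilo - 0.2 < 1.0 < ihi + 0.2
    assert fit.p_positive("x") > 0.99
    pred = fit.predict(pd.DataFrame({"x": [0.2, 1.0, 1.8]}))
    assert pred["mean"].is_monotonic_increasing
    assert np.all(pred["hpdi_lower"] < pred["mean"]) and np.all(pred["mean"] < pred["hpdi_upper"])


# ---------------------------------------------------------------------------
# LOO model selection


def test_loo_selects_informative_covariate():
    rng = np.random.default_rng(21)
    n = 15
    x1 = rng.uniform(0, 1, n)
    x2 = rng.uniform(0, 1, n)
    site = np.tile(["A", "B", "C"], n // 3)
    y = 0.5 + 3.0 * x1 + rng.normal(0, 0.2, n)
    df = pd.DataFrame({"site": site, "x1": x1, "x2": x2, "y": y})
    cands = [
        ModelSpec(response="y", family="gaussian", fixed=("x1",)),
        ModelSpec(response="y", family="gaussian", fixed=("x2",)),
        ModelSpec(response="y", family="gaussian", fixed=("x1", "x2")),
    ]
    res = loo_select(cands, df, seed=3)
    assert "x1" in res.best.fixed
    tbl = res.table
    assert list(tbl.columns) == ["model", "n_covariates", "elpd_loo", "rank"]
    assert tbl["elpd_loo"].is_monotonic_decreasing
    assert tbl.loc[tbl["model"] == "y~x2", "elpd_loo"].iloc[0] < tbl["elpd_loo"].max() - 2
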
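"""Covariate-adjusted group inference, multiplicity, correlations,
demographic balance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegmst import (ancova, bonferroni, demographics, regional_ttest,
                    severity_correlation)
from eegmst.stats import DegenerateDesignWarning


def _ancova_oracle_F(y, g, covs):
    """Group F by explicit normal equations: full model vs model without
    the group column (extra-sum-of-squares)."""
    X_full = np.column_stack([np.ones_like(y), g] + covs)
    X_red = np.column_stack([np.ones_like(y)] + covs)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return resid @ resid

    rss_f, rss_r = rss(X_full), rss(X_red)
    df_res = len(y) - X_full.shape[1]
    F = (rss_r - rss_f) / (rss_f / df_res)
    return F, df_res, (rss_r - rss_f) / rss_r * 0 + (rss_r - rss_f) / ((rss_r - rss_f) + rss_f)


# ---------------------------------------------------------------------------
# ANCOVA


def test_ancova_matches_normal_equation_oracle():
    rng = np.random.default_rng(5)
    n = 8
    g = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    age = rng.uniform(18, 30, n)
    sex = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
    power = rng.uniform(0.5, 2.0, n)
    y = 1.0 + 0.5 * g + 0.05 * age + 0.2 * sex + rng.normal(0, 0.3, n)
    groups = np.where(g == 1, "IA", "HC")
    res = ancova(y, groups,
                 covariates=pd.DataFrame({"age": age, "sex": sex,
                                          "band_power": power}),
                 log_power=False)
    F, df_res, eta = _ancova_oracle_F(y, g, [age, sex, power])
    assert res.stat == pytest.approx(F, abs=1e-10)
    assert res.df == (1, df_res)
    assert res.p == pytest.approx(sps.f.sf(F, 1, df_res), abs=1e-12)
    assert res.effect == pytest.approx(eta, abs=1e-10)


def test_ancova_reduces_to_anova_without_covariates():
    rng = np.random.default_rng(6)
    y = rng.normal(0, 1, 20)
    groups = np.repeat(["IA", "HC"], 10)
    res = ancova(y, groups, covariates=None)
    F_ref, p_ref = sps.f_oneway(y[groups == "IA"], y[groups == "HC"])
    assert res.stat == pytest.approx(F_ref, rel=1e-10)
    assert res.p == pytest.approx(p_ref, rel=1e-10)


def test_ancova_perfect_separation_limit():
    y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
    groups = np.repeat(["HC", "IA"], 4)
    rng = np.random.default_rng(7)
    cov = pd.DataFrame({"age": rng.uniform(18, 25, 8)})
    res = ancova(y, groups, covariates=cov)
    assert res.p < 1e-10
    assert res.effect > 0.999999
    assert res.direction == "IA>HC"


def test_ancova_direction_sign():
    rng = np.random.default_rng(8)
    y = np.concatenate([rng.normal(5, 0.1, 10), rng.normal(1, 0.1, 10)])
    groups = np.repeat(["IA", "HC"], 10)
    assert ancova(y, groups).direction == "IA>HC"
    assert ancova(-y, groups).direction == "IA<HC"


def test_ancova_drops_zero_variance_covariate_with_warning():
    rng = np.random.default_rng(9)
    y = rng.normal(0, 1, 12)
    groups = np.repeat(["IA", "HC"], 6)
    cov = pd.DataFrame({"age": rng.uniform(18, 25, 12),
                        "sex": ["F"] * 12})
    with pytest.warns(DegenerateDesignWarning, match="sex"):
        res = ancova(y, groups, covariates=cov)
    assert np.isfinite(res.stat)


def test_ancova_input_validation():
    with pytest.raises(ValueError, match="two groups"):
        ancova(np.zeros(4), np.array(["A"] * 4))
    with pytest.raises(ValueError, match="2 subjects"):
        ancova(np.zeros(3), np.array(["IA", "IA", "HC"]))


def test_ancova_type_one_error_calibrated_under_null():
    """Identical group distributions with inert covariates: p-values are
    approximately uniform (rejection near the nominal rate)."""
    rng = np.random.default_rng(10)
    n_reps, n = 400, 24
    groups = np.repeat(["IA", "HC"], n // 2)
    ps = []
    for _ in range(n_reps):
        y = rng.normal(0, 1, n)
        cov = pd.DataFrame({"age": rng.uniform(18, 28, n),
                            "sex": rng.integers(0, 2, n).astype(float)})
        ps.append(ancova(y, groups, covariates=cov).p)
    ps = np.array(ps)
    rate = (ps < 0.05).mean()
    assert 0.02 <= rate <= 0.09   # ~3 SD band around 0.05 at 400 reps
    # gross uniformity: KS against U(0,1)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Bonferroni


def test_bonferroni_family_of_nine():
    adjusted, threshold = bonferroni([0.004, 0.5, 1.0], m=9)
    assert threshold == pytest.approx(0.05 / 9)
    assert f"{threshold:.3f}" == "0.006"
    assert adjusted[0] == pytest.approx(0.036)
    assert adjusted[1] == 1.0  # capped
    assert adjusted[2] == 1.0


def test_bonferroni_monotone_and_dominates_raw():
    p = np.linspace(0, 1, 21)
    for m in (1, 3, 9, 20):
        adj, _ = bonferroni(p, m=m)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= 0)
    a3, _ = bonferroni(p, m=3)
    a9, _ = bonferroni(p, m=9)
    assert np.all(a9 >= a3)


def test_bonferroni_invalid_inputs():
    with pytest.raises(ValueError):
        bonferroni([1.2])
    with pytest.raises(ValueError):
        bonferroni([0.5], m=0)


# ---------------------------------------------------------------------------
# regional t tests


def test_regional_ttest_matches_scipy_and_flags_boosted_node():
    rng = np.random.default_rng(11)
    labels = ["FP1", "FP2", "C3", "C4", "O1"]
    a = rng.normal(0.3, 0.05, size=(15, 5))
    b = rng.normal(0.3, 0.05, size=(15, 5))
    a[:, 2] += 0.2  # planted boost at C3 in group IA
    out = regional_ttest(a, b, labels, measure="degree")
    t_ref, p_ref = sps.ttest_ind(a[:, 2], b[:, 2], equal_var=True)
    row = out[out.channel == "C3"].iloc[0]
    assert row.t == pytest.approx(t_ref, abs=1e-12)
    assert row.p == pytest.approx(p_ref, abs=1e-12)
    assert row.p < 0.001 and row.direction == "IA>HC"
    flagged = set(out[out.p < 0.01].channel)
    assert "C3" in flagged


def test_regional_ttest_null_groups_mostly_unflagged():
    rng = np.random.default_rng(12)
    labels = [f"ch{i:02d}" for i in range(32)]
    a = rng.normal(0, 1, size=(20, 32))
    b = rng.normal(0, 1, size=(20, 32))
    out = regional_ttest(a, b, labels)
    assert (out.p < 0.05).sum() <= 6  # chance-level flags only


def test_regional_ttest_welch_flag_differs_under_heteroscedasticity():
    rng = np.random.default_rng(13)
    a = rng.normal(0, 1.0, size=(10, 3))
    b = rng.normal(0, 5.0, size=(25, 3))
    pooled = regional_ttest(a, b, ["x", "y", "z"], welch=False)
    welch = regional_ttest(a, b, ["x", "y", "z"], welch=True)
    assert not np.allclose(pooled.p, welch.p)


def test_regional_ttest_degenerate_and_size_errors():
    labels = ["a", "b"]
    const = np.ones((5, 2))
    out = regional_ttest(const, const, labels)
    assert out.p.isna().all()
    assert (out.direction == "degenerate").all()
    with pytest.raises(ValueError):
        regional_ttest(np.ones((1, 2)), np.ones((5, 2)), labels)


# ---------------------------------------------------------------------------
# severity correlation


def test_severity_correlation_exact_linear_cases():
    iat = np.arange(20, 80, 6, dtype=float)
    up = severity_correlation(2 * iat + 1, iat)
    assert up.stat == pytest.approx(1.0)
    down = severity_correlation(-iat, iat)
    assert down.stat == pytest.approx(-1.0)
    assert down.direction == "-"


def test_severity_correlation_matches_covariance_formula():
    rng = np.random.default_rng(14)
    x = rng.normal(0, 1, 10)
    y = rng.uniform(20, 80, 10)
    res = severity_correlation(x, y)
    r_ref = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert res.stat == pytest.approx(r_ref, abs=1e-12)
    t = r_ref * np.sqrt(8 / (1 - r_ref ** 2))
    assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 8), abs=1e-12)


def test_severity_correlation_validation():
    with pytest.raises(ValueError):
        severity_correlation(np.ones(5), np.arange(5.0))  # zero variance
    with pytest.raises(ValueError):
        severity_correlation(np.arange(2.0), np.arange(2.0))  # n < 3
    with pytest.raises(ValueError):
        severity_correlation(np.array([1, np.nan, 2.0]), np.arange(3.0))


# ---------------------------------------------------------------------------
# demographics


def test_demographics_chi_square_matches_hand_formula():
    meta = pd.DataFrame({
        "group": ["IA"] * 30 + ["HC"] * 30,
        "sex": ["M"] * 7 + ["F"] * 23 + ["M"] * 6 + ["F"] * 24,
        "age": np.r_[np.random.default_rng(1).normal(21, 2, 30),
                     np.random.default_rng(2).normal(20.5, 1.6, 30)],
        "iat": np.r_[np.random.default_rng(3).integers(50, 80, 30),
                     np.random.default_rng(4).integers(20, 50, 30)],
    })
    out = demographics(meta)
    # hand computation on the 2x2 table [[7,23],[6,24]] (rows IA/HC)
    obs = np.array([[23.0, 7.0], [24.0, 6.0]])  # F/M column order
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    chi2_hand = ((obs - expected) ** 2 / expected).sum()
    row = out[out.variable == "sex"].iloc[0]
    assert row.stat == pytest.approx(chi2_hand, abs=1e-12)
    assert out[out.variable == "iat"].iloc[0].p < 1e-10


def test_demographics_identical_groups_nonsignificant():
    base = pd.DataFrame({"age": np.linspace(19, 23, 10),
                         "iat": np.linspace(30, 70, 10),
                         "sex": ["M", "F"] * 5})
    meta = pd.concat([base.assign(group="IA"), base.assign(group="HC")])
    out = demographics(meta)
    assert (out[out.variable.isin(["age", "iat"])].p > 0.99).all()


def test_demographics_degenerate_sex_warns():
    meta = pd.DataFrame({
        "group": ["IA"] * 4 + ["HC"] * 4,
        "sex": ["F"] * 8,
        "age": np.arange(8, dtype=float) + 20,
        "iat": [55, 60, 65, 70, 25, 30, 35, 40],
    })
    with pytest.warns(DegenerateDesignWarning):
        out = demographics(meta)
    assert np.isnan(out[out.variable == "sex"].iloc[0].stat)
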
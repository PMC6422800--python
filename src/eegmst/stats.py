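"""Group-level inference on connectivity and tree metrics.

The primary comparison is a one-way ANCOVA per measure and band: a linear
model  measure ~ group + age + sex + band_power  in which the group term
carries 1 degree of freedom, so its F statistic equals the squared t of
the group coefficient and partial eta-squared is SS_group /
(SS_group + SS_residual).  Sex enters as a 0/1 covariate and band power
(that band's own power) is log-transformed by default for variance
stabilisation.  p-values are Bonferroni-corrected per band over the m
measures tested (m = 9: global PLI plus eight tree measures; threshold
0.05/9 ~ 0.006).

Regional comparisons use two-sample t tests per channel (pooled variance
by default, Welch behind a flag, uncorrected p with an optional
Benjamini-Hochberg column); severity associations use Pearson correlation
against the IAT score; and demographic balance checks use a two-sample t
(age, IAT) and a 2x2 Pearson chi-square without continuity correction
(sex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "ancova", "bonferroni", "regional_ttest",
           "severity_correlation", "demographics", "BONFERRONI_M",
           "DegenerateDesignWarning"]

#: Measures entering the per-band family: global PLI + 8 tree measures.
BONFERRONI_M = 9


class DegenerateDesignWarning(UserWarning):
    """A covariate or contingency cell was degenerate; the analysis adapted
    (covariate dropped / validity flag set) rather than failing."""


@dataclass
class StatResult:
    """One inferential result (ANCOVA F, t, Pearson r, or chi-square)."""

    measure: str
    band: str = ""
    stat_name: str = "F"
    stat: float = np.nan
    p: float = np.nan
    p_adjusted: float = np.nan
    effect: float = np.nan          # partial eta^2 for ANCOVA
    direction: str = "n.s."         # "IA>HC" | "IA<HC" | "n.s."
    df: tuple = ()
    notes: str = ""
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)


def _encode_sex(sex: pd.Series | np.ndarray) -> np.ndarray:
    s = pd.Series(sex)
    if s.dtype == object or s.dtype.name == "category":
        return (s.astype(str).str.upper().str[0] == "M").to_numpy(float)
    return s.to_numpy(float)


def ancova(values: np.ndarray, group: np.ndarray,
           covariates: pd.DataFrame | dict | None = None,
           measure: str = "", band: str = "",
           log_power: bool = True, alpha: float = 0.05) -> StatResult:
    """One-way ANCOVA of a per-subject measure on group with covariates.

    Parameters
    ----------
    values
        Per-subject measure (n,).
    group
        Per-subject labels; exactly two levels, "IA" and "HC" (or any two,
        sorted so that the direction string is level1 vs level0 with
        "IA"/"HC" recognised specially).
    covariates
        Columns such as age, sex, band_power.  Sex is 0/1-encoded, band
        power log-transformed when ``log_power``.  Zero-variance covariates
        are dropped with a warning instead of producing a singular design.

    Returns
    -------
    StatResult with the group-term F (1 numerator df), its p from
    F(1, n - k - 1), partial eta-squared, and the direction of the
    adjusted group difference.
    """
    y = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    # put IA (case) second so its coefficient sign reads "IA minus HC"
    if "IA" in levels and "HC" in levels:
        levels = ["HC", "IA"]
    g = (group == levels[1]).astype(float)
    if min(g.sum(), (1 - g).sum()) < 2:
        raise ValueError("need >= 2 subjects per group")

    cols: list[np.ndarray] = [g]
    names = ["group"]
    if covariates is not None:
        cov = pd.DataFrame(covariates).copy()
        for name in cov.columns:
            col = cov[name]
            if name == "sex":
                arr = _encode_sex(col)
            else:
                arr = col.to_numpy(float)
                if log_power and "power" in str(name):
                    if np.any(arr <= 0):
                        raise ValueError("band power must be positive to log")
                    arr = np.log(arr)
            if np.std(arr) == 0:
                warnings.warn(f"covariate {name!r} has zero variance; dropped",
                              DegenerateDesignWarning, stacklevel=2)
                continue
            cols.append(arr)
            names.append(str(name))
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    # group is a single-df term: F = t^2, same as the type-III group F
    t_group = fit.tvalues[1]
    F = float(t_group ** 2)
    df_res = int(fit.df_resid)
    p = float(sps.f.sf(F, 1, df_res))
    eta_p = F / (F + df_res) if np.isfinite(F) else np.nan

    ia_label, hc_label = levels[1], levels[0]
    res = StatResult(
        measure=measure, band=band, stat_name="F", stat=F, p=p,
        effect=float(eta_p), df=(1, df_res),
        direction=(f"{ia_label}>{hc_label}" if fit.params[1] > 0
                   else f"{ia_label}<{hc_label}") if p < alpha else "n.s.",
        group_means={lv: float(y[group == lv].mean()) for lv in levels},
        group_sds={lv: float(y[group == lv].std(ddof=1)) for lv in levels},
    )
    return res


def bonferroni(p_values: "list[float] | np.ndarray",
               m: int = BONFERRONI_M) -> tuple[np.ndarray, float]:
    """Bonferroni adjustment: min(1, p*m) and the family threshold 0.05/m.

    ``m`` defaults to the 9 measures of the per-band family and may exceed
    the number of p-values supplied (the family size is what counts).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m), 0.05 / m


def regional_ttest(values_a: np.ndarray, values_b: np.ndarray,
                   node_labels: list[str], measure: str = "degree",
                   band: str = "", welch: bool = False,
                   fdr: bool = True) -> pd.DataFrame:
    """Per-channel two-sample t tests of a nodal statistic between groups.

    Parameters
    ----------
    values_a, values_b
        (n_subjects, n_nodes) nodal values for the two groups (a = IA).
    welch
        Use Welch's unequal-variance t instead of the pooled-variance
        default.
    fdr
        Add a Benjamini-Hochberg adjusted column (the primary report stays
        uncorrected).

    Channels with zero variance in both groups get NaN statistics and a
    "degenerate" note.
    """
    a = np.atleast_2d(np.asarray(values_a, float))
    b = np.atleast_2d(np.asarray(values_b, float))
    if a.shape[1] != len(node_labels) or b.shape[1] != len(node_labels):
        raise ValueError("value columns must match node_labels")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant columns are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=not welch)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    out = pd.DataFrame({
        "channel": node_labels, "measure": measure, "band": band,
        "t": t, "p": p,
        "mean_IA": a.mean(axis=0), "mean_HC": b.mean(axis=0),
        "direction": np.where(np.isnan(t), "degenerate",
                              np.where(t > 0, "IA>HC", "IA<HC")),
    })
    if fdr:
        ok = ~np.isnan(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out["p_fdr"] = q
    return out


def severity_correlation(values: np.ndarray, iat: np.ndarray,
                         measure: str = "", band: str = "") -> StatResult:
    """Pearson correlation of a measure with IAT severity scores.

    Two-sided p from the t transform with n - 2 df.
    """
    x = np.asarray(values, float)
    y = np.asarray(iat, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and iat must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return StatResult(measure=measure, band=band, stat_name="r",
                      stat=float(r), p=float(p), df=(x.size - 2,),
                      direction="+" if r > 0 else "-")


def demographics(meta: pd.DataFrame, chi2_correction: bool = False) -> pd.DataFrame:
    """Group-balance checks on the metadata table.

    age and iat: two-sample t test (pooled).  sex: 2x2 Pearson chi-square,
    by default without Yates continuity correction; a validity warning is
    attached when any expected cell count falls below 5.
    """
    if set(meta["group"]) != {"IA", "HC"}:
        raise ValueError("metadata must contain both IA and HC groups")
    ia = meta[meta["group"] == "IA"]
    hc = meta[meta["group"] == "HC"]
    rows = []
    for col in ("age", "iat"):
        t, p = sps.ttest_ind(ia[col], hc[col], equal_var=True)
        rows.append({"variable": col, "test": "t", "stat": float(t),
                     "p": float(p),
                     "IA": f"{ia[col].mean():.2f}±{ia[col].std(ddof=1):.2f}",
                     "HC": f"{hc[col].mean():.2f}±{hc[col].std(ddof=1):.2f}",
                     "note": ""})
    table = pd.crosstab(meta["group"], meta["sex"]).reindex(
        index=["IA", "HC"]).fillna(0).to_numpy()
    note = ""
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate sex distribution: chi-square invalid",
                      DegenerateDesignWarning, stacklevel=2)
        chi2, p = np.nan, np.nan
        note = "degenerate"
    else:
        chi2, p, _, expected = sps.chi2_contingency(
            table, correction=chi2_correction)
        if (expected < 5).any():
            note = "expected cell < 5"
            warnings.warn("chi-square validity: expected cell count < 5",
                          DegenerateDesignWarning, stacklevel=2)
    counts_ia = "/".join(str(int(c)) for c in table[0]) if table.size else ""
    counts_hc = "/".join(str(int(c)) for c in table[1]) if table.size else ""
    rows.append({"variable": "sex", "test": "chi2", "stat": float(chi2),
                 "p": float(p), "IA": counts_ia, "HC": counts_hc,
                 "note": note})
    return pd.DataFrame(rows)
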
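"""Cohort statistics battery for nested lesion definitions and cognition.

Within-group comparisons across the three nested definitions use
Cochran's Q (binary prevalence and per-decade burden) and the Friedman
test with Kendall's W (counts and volumes).  Between-group comparisons
use Yates-corrected chi-square with Cramer's phi, Fisher's exact test
with the conditional maximum-likelihood odds ratio (the estimator
exact-test software reports; the sample cross-product ratio differs), and
Mann-Whitney U with the r = |Z|/sqrt(N) effect size.  Cohort-level
regression models estimate IQ/WMI/PSI (ordinary least squares) or
impairment (logistic) from an increasingly complex ladder of lesion
metrics alongside pre-selected covariates, with variance-inflation
screening of the lesion terms.

Effect-size conventions: Kendall's W = Q / (n (k-1)); Cramer's phi =
sqrt(X^2 / N); Cohen's d uses the pooled SD; Mann-Whitney r uses the
tie-corrected normal approximation.  No multiple-comparison correction
is applied by default (the design deliberately maximises sensitivity);
a Holm correction can be switched on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "StatReport",
    "cochran_q",
    "friedman_kendall",
    "kendalls_w",
    "chi2_2x2",
    "fisher_exact",
    "mann_whitney_r",
    "spearman_screen",
    "impute_group_mean",
    "cohens_d",
    "group_summary",
    "ModelSpec",
    "ModelReport",
    "regression_battery",
    "nested_status_matrix",
]


@dataclass
class StatReport:
    """One test: statistic, degrees of freedom, p, effect size."""

    test: str
    statistic: float
    df: float | None
    p: float
    effect_name: str | None = None
    effect: float | None = None
    ci: tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def nested_status_matrix(n_total: int, positives: tuple[int, int, int]) -> np.ndarray:
    """Subject x definition 0/1 matrix implied by nested per-definition
    positive counts (restrictive subset of traditional subset of liberal)."""
    l, t, r = positives
    if not n_total >= l >= t >= r >= 0:
        raise ValueError(f"counts must nest within n={n_total}, got {positives}")
    rows = (
        [(1, 1, 1)] * r
        + [(1, 1, 0)] * (t - r)
        + [(1, 0, 0)] * (l - t)
        + [(0, 0, 0)] * (n_total - l)
    )
    return np.array(rows, dtype=int)


def cochran_q(m: np.ndarray) -> StatReport:
    """Cochran's Q test for marginal homogeneity of k matched binary
    outcomes: Q = (k-1)(k sum Cj^2 - N^2) / (k sum Ri - sum Ri^2) with
    column totals Cj, row totals Ri, N the grand total; df = k - 1.
    Rows with all-equal responses contribute nothing; an all-constant
    matrix yields Q = 0, p = 1.
    """
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 1:
        raise ValueError("need an n x k matrix with k >= 2")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    n, k = m.shape
    C = m.sum(axis=0).astype(float)
    R = m.sum(axis=1).astype(float)
    N = C.sum()
    denom = k * R.sum() - (R**2).sum()
    if denom == 0:
        return StatReport("cochran_q", 0.0, k - 1, 1.0, extras={"n": n, "k": k})
    q = (k - 1) * (k * (C**2).sum() - N**2) / denom
    p = float(sps.chi2.sf(q, k - 1))
    return StatReport("cochran_q", float(q), k - 1, p, extras={"n": n, "k": k})


def kendalls_w(q_statistic: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance from a Friedman chi-square."""
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 and k >= 2")
    return float(q_statistic) / (n * (k - 1))


def friedman_kendall(m: np.ndarray) -> StatReport:
    """Friedman test across k matched conditions with average-rank tie
    handling, reported with Kendall's W."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2")
    if m.shape[0] < 2:
        raise ValueError("Friedman test needs at least 2 rows")
    n, k = m.shape
    res = sps.friedmanchisquare(*(m[:, j] for j in range(k)))
    w = kendalls_w(res.statistic, n, k)
    return StatReport(
        "friedman",
        float(res.statistic),
        k - 1,
        float(res.pvalue),
        effect_name="kendall_w",
        effect=w,
        extras={"n": n, "k": k},
    )


def chi2_2x2(table: np.ndarray, yates: bool = True) -> StatReport:
    """Chi-square test on a 2x2 table (Yates continuity correction by
    default) with Cramer's phi = sqrt(X^2 / N)."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 non-negative table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    res = sps.chi2_contingency(table, correction=yates)
    n = table.sum()
    phi = float(np.sqrt(res.statistic / n))
    return StatReport(
        "chi2_2x2",
        float(res.statistic),
        1,
        float(res.pvalue),
        effect_name="cramers_phi",
        effect=phi,
        extras={"yates": yates, "n": int(n)},
    )


def _cmle_odds_ratio(table: np.ndarray) -> float:
    """Conditional MLE of the odds ratio under the noncentral
    hypergeometric model; inf/0 at the support boundary."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    if a == hi:
        return np.inf
    if a == lo:
        return 0.0
    return float(_scipy_odds_ratio(table, kind="conditional").statistic)


def fisher_exact(table: np.ndarray) -> StatReport:
    """Fisher's exact test (two-sided) with the conditional-MLE odds
    ratio.  Tables whose observed cell sits at the support boundary
    (e.g. a zero cell) have an unbounded estimate, reported as NaN with
    an ``or_unbounded`` flag."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 non-negative table")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    oddsr = _cmle_odds_ratio(table)
    unbounded = not np.isfinite(oddsr) or oddsr == 0.0
    return StatReport(
        "fisher_exact",
        float("nan"),
        None,
        float(p),
        effect_name="odds_ratio_cmle",
        effect=float("nan") if unbounded else oddsr,
        extras={"or_unbounded": unbounded},
    )


def mann_whitney_r(x, y, method: str = "asymptotic") -> StatReport:
    """Mann-Whitney U with r = |Z|/sqrt(n1+n2) from the tie-corrected
    normal approximation.  ``method='exact'`` replaces the p-value with
    the exact permutation value (tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu_u = n1 * n2 / 2.0
    z = 0.0 if var_u == 0 else (u - mu_u) / np.sqrt(var_u)
    p = float(2 * sps.norm.sf(abs(z)))
    if method == "exact":
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    r = abs(z) / np.sqrt(n)
    return StatReport(
        "mann_whitney_u",
        u,
        None,
        min(p, 1.0),
        effect_name="rank_biserial_r",
        effect=float(r),
        extras={"z": float(z), "method": method},
    )


def spearman_screen(
    table: pd.DataFrame, variables: list[str], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations on complete pairs.

    Returns (rho, p, significant) frames; constant variables yield NaN
    entries.  Significance is at uncorrected ``alpha``.
    """
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for a, b in itertools.combinations(variables, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = sps.spearmanr(sub[a], sub[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    sig = (pval < alpha) & np.isfinite(rho)
    np.fill_diagonal(sig.values, False)
    return rho, pval, sig


def impute_group_mean(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> tuple[pd.DataFrame, int]:
    """Replace missing values by the observed mean of the row's group.

    Groups with no missing entries are untouched; a group that is all
    missing (and would need imputation) raises.  Returns the imputed
    table and the number of imputed entries.
    """
    out = table.copy()
    n_imputed = 0
    for g, sub in table.groupby(group_col):
        missing = sub[variable].isna()
        if not missing.any():
            continue
        observed = sub.loc[~missing, variable]
        if observed.empty:
            raise ValueError(f"group {g!r}: all values of {variable!r} missing")
        out.loc[sub.index[missing], variable] = observed.mean()
        n_imputed += int(missing.sum())
    return out, n_imputed


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    sp = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def group_summary(table: pd.DataFrame) -> dict[str, StatReport]:
    """Demographic/cognitive between-group comparisons: chi-square for
    sex, Mann-Whitney for age/education/SpO2, Welch t with Cohen's d for
    the cognitive scores, Fisher's exact for impairment."""
    sca = table[table["group"] == "sca"]
    ctl = table[table["group"] == "control"]
    if sca.empty or ctl.empty:
        raise ValueError("both groups must be non-empty")
    out: dict[str, StatReport] = {}

    sex_tab = np.array(
        [
            [int(sca["sex"].sum()), int((1 - sca["sex"]).sum())],
            [int(ctl["sex"].sum()), int((1 - ctl["sex"]).sum())],
        ]
    )
    out["sex"] = chi2_2x2(sex_tab)

    for var in ("age", "education_decile", "spo2"):
        x, y = sca[var].dropna(), ctl[var].dropna()
        out[var] = mann_whitney_r(x, y)

    for var in ("iq", "wmi", "psi"):
        x, y = sca[var].dropna(), ctl[var].dropna()
        t, p = sps.ttest_ind(x, y, equal_var=False)
        nu = _welch_df(x, y)
        out[var] = StatReport(
            "welch_t",
            float(t),
            nu,
            float(p),
            effect_name="cohens_d",
            effect=cohens_d(x, y),
        )

    imp_tab = np.array(
        [
            [int(sca["impaired"].sum()), int((1 - sca["impaired"]).sum())],
            [int(ctl["impaired"].sum()), int((1 - ctl["impaired"]).sum())],
        ]
    )
    try:
        out["impaired"] = fisher_exact(imp_tab)
    except ValueError:
        pass
    return out


def _welch_df(x, y) -> float:
    v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    return float(
        (v1 + v2) ** 2 / (v1**2 / (x.size - 1) + v2**2 / (y.size - 1))
    )


# --------------------------------------------------------------------------
# regression model ladder


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model ladder.

    ``model_id`` selects the lesion-metric predictor set: 1 presence
    indicator only; 2 adds its interaction with mean-centred SCA status;
    3 presence + log lesion count; 4 adds both interactions; 5 presence
    + log lesion volume; 6 adds both interactions.  Covariates are age,
    sex, intracranial volume, SpO2 and education decile (plus hemoglobin
    and minus the group terms in SCA-only runs).
    """

    outcome: str = "iq"  # iq | wmi | psi | impaired
    definition: str = "liberal"  # liberal | traditional | restrictive
    model_id: int = 1
    subset: str = "all"  # all | sca

    def __post_init__(self) -> None:
        if self.model_id not in range(1, 7):
            raise ValueError("model_id must be 1-6")
        if self.outcome not in ("iq", "wmi", "psi", "impaired"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.definition not in ("liberal", "traditional", "restrictive"):
            raise ValueError(f"unknown definition {self.definition!r}")
        if self.subset not in ("all", "sca"):
            raise ValueError("subset must be 'all' or 'sca'")


@dataclass
class ModelReport:
    spec: ModelSpec
    params: pd.DataFrame | None  # coef, se, stat, p, ci_low, ci_high, sr
    lesion_terms: list[str]
    vif: dict[str, float]
    dropped: list[str]
    n: int
    r_squared: float | None = None
    error: str | None = None


def _design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    df = table.copy()
    if spec.subset == "sca":
        df = df[df["group"] == "sca"].copy()
    d = spec.definition
    df["sci_yn"] = df[f"sci_{d}"].astype(float)
    df["sci_log_number"] = np.log1p(df[f"n_{d}"].astype(float))
    df["sci_log_volume"] = np.log1p(df[f"vol_{d}"].astype(float))

    covars = ["age", "sex", "icv_cm3", "spo2", "education_decile"]
    df, _ = impute_group_mean(df, "spo2")
    if spec.subset == "sca":
        df, _ = impute_group_mean(df, "hemoglobin")
        covars.append("hemoglobin")
        lesion = {
            1: ["sci_yn"],
            2: ["sci_yn"],
            3: ["sci_yn", "sci_log_number"],
            4: ["sci_yn", "sci_log_number"],
            5: ["sci_yn", "sci_log_volume"],
            6: ["sci_yn", "sci_log_volume"],
        }[spec.model_id]
    else:
        df["sca"] = (df["group"] == "sca").astype(float)
        df["sca_c"] = df["sca"] - df["sca"].mean()
        covars.append("sca")
        base = {
            1: ["sci_yn"],
            2: ["sci_yn"],
            3: ["sci_yn", "sci_log_number"],
            4: ["sci_yn", "sci_log_number"],
            5: ["sci_yn", "sci_log_volume"],
            6: ["sci_yn", "sci_log_volume"],
        }[spec.model_id]
        lesion = list(base)
        if spec.model_id in (2, 4, 6):
            for term in base:
                name = f"{term}_x_sca"
                df[name] = df[term] * df["sca_c"]
                lesion.append(name)

    cols = lesion + covars
    sub = df[[spec.outcome] + cols].dropna()
    y = sub[spec.outcome]
    X = sm.add_constant(sub[cols], has_constant="add")
    return y, X, lesion


def _vif_screen(X: pd.DataFrame, lesion_terms: list[str], limit: float = 5.0):
    """VIF for the lesion terms; binary presence indicators exceeding the
    limit are flagged for dropping."""
    vifs: dict[str, float] = {}
    arr = X.values
    for term in lesion_terms:
        j = list(X.columns).index(term)
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                vifs[term] = float(variance_inflation_factor(arr, j))
        except Exception:
            vifs[term] = float("inf")
    drop = [
        t
        for t in lesion_terms
        if t.startswith("sci_yn") and vifs.get(t, 0.0) > limit
    ]
    # only drop indicators when a continuous quantifier remains in the model
    has_quantifier = any(
        ("number" in t or "volume" in t) for t in lesion_terms
    )
    return vifs, (drop if has_quantifier else [])


def regression_battery(
    table: pd.DataFrame,
    specs: list[ModelSpec],
    vif_limit: float = 5.0,
    alpha: float = 0.05,
) -> list[ModelReport]:
    """Fit the model ladder: OLS for continuous outcomes, logistic for
    impairment, with log-transformed count/volume predictors,
    mean-centred group interactions, and VIF-based dropping of binary
    indicators (VIF > 5) when a continuous quantifier is present."""
    reports: list[ModelReport] = []
    for spec in specs:
        y, X, lesion_terms = _design(table, spec)
        n = len(y)
        if n <= X.shape[1]:
            reports.append(
                ModelReport(spec, None, lesion_terms, {}, [], n, error="n <= parameters")
            )
            continue
        vifs, drop = _vif_screen(X, lesion_terms, vif_limit)
        if drop:
            X = X.drop(columns=drop)
            lesion_terms = [t for t in lesion_terms if t not in drop]
        try:
            if spec.outcome == "impaired":
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                r2 = None
            else:
                fit = sm.OLS(y, X).fit()
                r2 = float(fit.rsquared)
        except Exception as exc:  # separation, singular design
            reports.append(
                ModelReport(spec, None, lesion_terms, vifs, drop, n, error=str(exc))
            )
            continue
        ci = fit.conf_int(alpha)
        params = pd.DataFrame(
            {
                "coef": fit.params,
                "se": fit.bse,
                "stat": fit.tvalues,
                "p": fit.pvalues,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
        if spec.outcome != "impaired":
            # semi-partial correlation of each lesion term with the outcome
            sr = {}
            with np.errstate(invalid="ignore"):
                for term in lesion_terms:
                    t_val = fit.tvalues[term]
                    sr[term] = float(
                        t_val * np.sqrt((1 - fit.rsquared) / fit.df_resid)
                    )
            params["semipartial_r"] = pd.Series(sr)
        reports.append(
            ModelReport(
                spec,
                params,
                lesion_terms,
                vifs,
                drop,
                n,
                r_squared=r2,
            )
        )
    return reports
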
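"""Cohort-level statistics on the hub markers.

Reproduces the analysis battery applied to the clinical cohorts: a median
split into short/long survival, per-marker two-sample tests (pooled-variance
t test or Wilcoxon rank-sum) with Bonferroni correction over the five
markers, covariate-adjusted linear regression (marker ~ group + age + sex),
K-means clustering with Calinski–Harabasz model selection over k = 1..9,
Kaplan–Meier / logrank / Cox survival comparison, and pairwise marker
correlations.

Survival estimation uses the standard right-censoring product-limit
(Kaplan–Meier) estimator — the form the general nonparametric
interval-censoring estimator reduces to when only right censoring is
present — and Cox fits use Efron tie handling via lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .markers import MARKER_NAMES

logger = logging.getLogger(__name__)

BONFERRONI_FACTOR = len(MARKER_NAMES)  # five markers tested
DEFAULT_K_RANGE = tuple(range(1, 10))  # cluster counts 1..9


# ------------------------------------------------------------------ splits
def split_at_median_survival(t: pd.DataFrame) -> pd.DataFrame:
    """Label subjects short/long survival at the cohort median.

    Subjects at or below the median go to ``short``, strictly above to
    ``long``.  Raises when all times are identical (no split exists).
    """
    if len(t) < 2:
        raise ValueError("need >= 2 subjects to split")
    times = t["survival_months"].to_numpy(dtype=float)
    med = float(np.median(times))
    if np.all(times == times[0]):
        raise ValueError("all survival times identical: median split impossible")
    out = t.copy()
    out["survival_group"] = np.where(times <= med, "short", "long")
    return out


# ------------------------------------------------------------- group tests
@dataclass
class TestReport:
    """Per-marker group-difference tests with Bonferroni adjustment."""

    kind: str
    group: str
    table: pd.DataFrame  # marker, statistic, p, p_adjusted, direction, flag

    def significant(self, alpha: float = 0.05) -> list:
        return self.table.loc[self.table["p_adjusted"] < alpha, "marker"].tolist()


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum z via the normal approximation with tie correction."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    combined = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0, 1.0
    z = (res.statistic - mu) / np.sqrt(sigma2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def group_difference_tests(
    t: pd.DataFrame, group: str, kind: str = "t_test", markers=MARKER_NAMES
) -> TestReport:
    """Two-sided per-marker tests between the two levels of ``group``.

    ``kind='t_test'`` uses the pooled-variance two-sample t test,
    ``kind='ranksum'`` the Wilcoxon rank-sum normal approximation with tie
    correction.  Adjusted p = min(1, 5 p) over the five markers.
    """
    levels = sorted(t[group].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"group {group} must have exactly 2 levels, got {levels}")
    a_mask = t[group] == levels[0]
    b_mask = t[group] == levels[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("both groups need >= 2 subjects")

    rows = []
    for marker in markers:
        a = t.loc[a_mask, marker].to_numpy(dtype=float)
        b = t.loc[b_mask, marker].to_numpy(dtype=float)
        flag = ""
        if np.std(a) == 0 and np.std(b) == 0:
            stat, p, flag = 0.0, 1.0, "zero_variance"
        elif kind == "t_test":
            res = stats.ttest_ind(a, b, equal_var=True)
            stat, p = float(res.statistic), float(res.pvalue)
        elif kind == "ranksum":
            stat, p = _rank_sum_z(a, b)
        else:
            raise ValueError("kind must be 't_test' or 'ranksum'")
        rows.append(
            {
                "marker": marker,
                "statistic": stat,
                "p": p,
                "p_adjusted": min(1.0, BONFERRONI_FACTOR * p),
                "direction": f"{levels[0]}>{levels[1]}" if np.mean(a) > np.mean(b) else f"{levels[1]}>{levels[0]}",
                "flag": flag,
            }
        )
    return TestReport(kind=kind, group=group, table=pd.DataFrame(rows))


def adjusted_regression(t: pd.DataFrame, group: str, markers=MARKER_NAMES) -> pd.DataFrame:
    """OLS of each marker on group with age and sex as covariates.

    Returns the group-coefficient estimate, its t statistic and two-sided p
    per marker.  Sex enters as a categorical covariate (reference level F,
    alphabetical); the group indicator is categorical with its first
    (alphabetical) level as reference.
    """
    df = t.copy()
    rows = []
    for marker in markers:
        formula = f"{marker} ~ C({group}) + age_years + C(sex)"
        model = smf.ols(formula, data=df)
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            bad = [n for n in model.exog_names]
            raise ValueError(f"design matrix rank deficient; columns: {bad}")
        res = model.fit()
        term = [n for n in res.params.index if n.startswith(f"C({group})")][0]
        rows.append(
            {
                "marker": marker,
                "coef": float(res.params[term]),
                "t": float(res.tvalues[term]),
                "p": float(res.pvalues[term]),
                "term": term,
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- clustering
@dataclass
class ClusterReport:
    chosen_k: int
    labels: np.ndarray  # labels at the CH-chosen k
    labels_k2: np.ndarray  # the two-cluster solution (survival contrast)
    ch_scores: dict
    cluster_names: dict  # k2 label -> low-PMI / high-PMI
    ch_ratio: float  # best CH / runner-up CH; near 1 = weak structure

    def named_labels(self) -> np.ndarray:
        """low-/high-PMI names on the two-cluster solution."""
        return np.array([self.cluster_names[l] for l in self.labels_k2])


def cluster_markers(
    t: pd.DataFrame, k_range=DEFAULT_K_RANGE, seed: int = 0, markers=MARKER_NAMES
) -> ClusterReport:
    """K-means over z-scored markers with Calinski–Harabasz selection.

    Scans k in ``k_range`` (default 1..9; k = 1 has no defined index and is
    treated as -inf, k larger than n-1 is skipped), 10 restarts per k.  The
    two-cluster solution — the basis of the low-/high-PMI survival contrast
    — is always computed and named by mean directional heterogeneity
    (higher -> high-PMI, the poor-prognosis direction); the CH scan is the
    model-selection diagnostic reported alongside.
    """
    x = t[list(markers)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("markers contain NaN; apply exclusions first")
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    ch_scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 1 or k > len(x) - 1:
            logger.warning("skipping k=%d (cohort of %d)", k, len(x))
            continue
        if k == 1:
            ch_scores[1] = -np.inf
            labelings[1] = np.zeros(len(x), dtype=int)
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
        labelings[k] = km.labels_
        ch_scores[k] = float(calinski_harabasz_score(z, km.labels_))

    finite = {k: v for k, v in ch_scores.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no k in range produced a defined Calinski-Harabasz index")
    chosen = max(finite, key=finite.get)
    ordered = sorted(finite.values(), reverse=True)
    ch_ratio = ordered[0] / ordered[1] if len(ordered) > 1 else np.inf

    if 2 in labelings:
        labels_k2 = labelings[2]
    else:
        labels_k2 = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z).labels_
    mean_dir = [t.loc[labels_k2 == l, "dir_het"].mean() for l in (0, 1)]
    hi = int(np.argmax(mean_dir))
    names = {hi: "high-PMI", 1 - hi: "low-PMI"}
    return ClusterReport(
        chosen_k=chosen,
        labels=labelings[chosen],
        labels_k2=labels_k2,
        ch_scores=ch_scores,
        cluster_names=names,
        ch_ratio=ch_ratio,
    )


# ---------------------------------------------------------------- survival
@dataclass
class SurvivalReport:
    group: str
    levels: list
    km_curves: dict  # level -> DataFrame(time, survival)
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple
    cox_p: float
    coef: float
    n_events: dict

    def summary(self) -> str:
        lo, hi = self.hr_ci
        return (
            f"{self.levels[1]} vs {self.levels[0]}: HR {self.hazard_ratio:.2f} "
            f"(95% CI {lo:.2f}-{hi:.2f}, p={self.cox_p:.2g}); "
            f"logrank chi2 {self.logrank_statistic:.2f} (p={self.logrank_p:.2g})"
        )


def survival_compare(t: pd.DataFrame, group: str) -> SurvivalReport:
    """Kaplan–Meier curves, logrank test and Cox HR between two groups.

    The Cox model is fit on the binary group indicator (second level coded 1,
    so HR > 1 means that level has the higher hazard) with Efron tie
    handling; the CI is the Wald 95% interval.
    """
    levels = sorted(t[group].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"group {group} must have exactly 2 levels, got {levels}")
    n_events = {}
    km_curves = {}
    for lev in levels:
        sub = t[t[group] == lev]
        n_events[lev] = int(sub["event"].sum())
        if n_events[lev] < 1:
            raise ValueError(f"group level {lev} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["survival_months"], event_observed=sub["event"], label=str(lev))
        km_curves[lev] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )

    a = t[t[group] == levels[0]]
    b = t[t[group] == levels[1]]
    lr = logrank_test(
        a["survival_months"], b["survival_months"], event_observed_A=a["event"], event_observed_B=b["event"]
    )

    cox_df = pd.DataFrame(
        {
            "T": t["survival_months"].to_numpy(dtype=float),
            "E": t["event"].to_numpy(dtype=int),
            "g": (t[group] == levels[1]).astype(int).to_numpy(),
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(cox_df, duration_col="T", event_col="E")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    coef = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    hr = float(np.exp(coef))
    ci = (float(np.exp(coef - 1.959964 * se)), float(np.exp(coef + 1.959964 * se)))
    return SurvivalReport(
        group=group,
        levels=list(levels),
        km_curves=km_curves,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=ci,
        cox_p=float(cph.summary.loc["g", "p"]),
        coef=coef,
        n_events=n_events,
    )


# ------------------------------------------------------------ correlations
def marker_correlations(t: pd.DataFrame, markers=MARKER_NAMES) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and R² between markers.

    Zero-variance markers get NaN (flagged with a warning).
    """
    if len(t) < 3:
        raise ValueError("need >= 3 subjects for correlations")
    sub = t[list(markers)].astype(float)
    zero_var = [m for m in markers if sub[m].std() == 0]
    if zero_var:
        logger.warning("zero-variance markers, correlations undefined: %s", zero_var)
    r = sub.corr(method="pearson")
    for m in zero_var:
        r.loc[m, :] = np.nan
        r.loc[:, m] = np.nan
    return r, r**2
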
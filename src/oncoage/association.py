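"""Age-association statistics: the screen-then-adjust regression cascade.

Per-cohort analyses follow a two-stage design: a simple (age-only)
regression per cohort, Benjamini-Hochberg correction across cohorts, and
a covariate-adjusted multiple regression for the cohorts that screen in
(adjusted p < 0.05).  Binary outcomes route through ordinary logistic
regression with a Firth-penalized fallback whenever separation is
detected.  Effect sizes for binary outcomes are reported as odds ratio
per year of age with Wald 95% confidence intervals.

Covariate handling: candidates missing in >= 10% of the cohort are
dropped, constants are dropped, categorical covariates are
dummy-encoded against the most frequent level with levels under five
samples pooled into 'other', and fits are complete-case.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .firth import ConvergenceError, FirthLogit, detect_separation

ALPHA_DEFAULT = 0.05
MAX_MISSING_DEFAULT = 0.10
MIN_LEVEL_COUNT = 5
PAN_CANCER_COVARIATES = ("gender", "race", "cancer_type")


class SeparationError(RuntimeError):
    """ML logistic fit abandoned: data are (quasi-)completely separated."""


@dataclass
class AssociationResult:
    """One fitted age term."""

    outcome: str
    cohort: str
    stage: str  # screen | adjusted
    method: str  # ols | logistic | firth
    n_used: int
    coefficient: float
    ci_low: float
    ci_high: float
    p: float
    or_per_year: float = np.nan
    or_ci_low: float = np.nan
    or_ci_high: float = np.nan
    adj_p: float = np.nan
    bh_family: str = ""
    covariates: tuple = field(default_factory=tuple)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "cohort": self.cohort,
            "stage": self.stage,
            "method": self.method,
            "n_used": self.n_used,
            "coefficient": self.coefficient,
            "or_per_year": self.or_per_year,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "p": self.p,
            "adj_p": self.adj_p,
            "bh_family": self.bh_family,
            "covariates": ",".join(self.covariates),
        }


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def covariate_select(
    clinical: pd.DataFrame,
    candidates,
    max_missing: float = MAX_MISSING_DEFAULT,
) -> list[str]:
    """Keep candidate covariates with missingness strictly below the cap.

    Constant covariates (a single observed level/value) carry no
    information and are dropped too.
    """
    if not list(candidates):
        raise ValueError("empty candidate list")
    n = len(clinical)
    kept = []
    for cov in candidates:
        if cov not in clinical.columns:
            continue
        col = clinical[cov]
        if n == 0 or col.isna().sum() / n >= max_missing:
            continue
        if col.dropna().nunique() <= 1:
            continue
        kept.append(cov)
    return kept


def _encode_categorical(col: pd.Series, min_level_count: int = MIN_LEVEL_COUNT):
    counts = col.value_counts()
    rare = counts[counts < min_level_count].index
    if len(rare) > 0:
        col = col.where(~col.isin(rare), other="other")
        counts = col.value_counts()
    reference = counts.idxmax()
    levels = [lv for lv in counts.index if lv != reference]
    return col, reference, levels


def build_design(
    data: pd.DataFrame,
    age_col: str,
    covariates,
    min_level_count: int = MIN_LEVEL_COUNT,
) -> pd.DataFrame:
    """Design matrix: const, age, then dummy-expanded covariates."""
    design = pd.DataFrame(index=data.index)
    design["const"] = 1.0
    design["age"] = data[age_col].astype(float)
    for cov in covariates:
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)
        else:
            col, _, levels = _encode_categorical(col.astype(str), min_level_count)
            for lv in levels:
                design[f"{cov}[{lv}]"] = (col == lv).astype(float)
    return design


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on earlier ones (incremental QR rank)."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        return []
    aliased = []
    basis = np.empty((arr.shape[0], 0))
    for j, name in enumerate(X.columns):
        col = arr[:, j : j + 1]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(col), 1.0):
            aliased.append(name)
        else:
            basis = np.hstack([basis, col])
    return aliased


def _complete_cases(data, outcome, age_col, covariates):
    cols = [outcome, age_col, *covariates]
    return data[cols].dropna()


def fit_linear(
    data: pd.DataFrame,
    outcome: str,
    covariates=(),
    age_col: str = "age",
    cohort: str = "",
    stage: str = "screen",
) -> AssociationResult:
    """OLS of a continuous outcome on age (+ covariates), complete cases."""
    d = _complete_cases(data, outcome, age_col, covariates)
    X = build_design(d, age_col, covariates)
    if len(d) <= X.shape[1]:
        raise ValueError(
            f"cohort {cohort or '?'}: n={len(d)} too small for {X.shape[1]} parameters"
        )
    aliased = _aliased_columns(X)
    if aliased:
        raise np.linalg.LinAlgError(f"rank-deficient design; aliased: {aliased}")
    res = sm.OLS(d[outcome].astype(float), X).fit()
    ci = res.conf_int().loc["age"]
    return AssociationResult(
        outcome=outcome,
        cohort=cohort,
        stage=stage,
        method="ols",
        n_used=int(res.nobs),
        coefficient=float(res.params["age"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(res.pvalues["age"]),
        covariates=tuple(covariates),
    )


def _binary_result(outcome, cohort, stage, method, n, params, ci, p, covariates):
    return AssociationResult(
        outcome=outcome,
        cohort=cohort,
        stage=stage,
        method=method,
        n_used=n,
        coefficient=float(params),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        or_per_year=float(np.exp(params)),
        or_ci_low=float(np.exp(ci[0])),
        or_ci_high=float(np.exp(ci[1])),
        p=float(p),
        covariates=tuple(covariates),
    )


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    covariates=(),
    age_col: str = "age",
    cohort: str = "",
    stage: str = "screen",
) -> AssociationResult:
    """ML logistic fit; raises SeparationError when ML would diverge."""
    d = _complete_cases(data, outcome, age_col, covariates)
    y = d[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"cohort {cohort or '?'}: single-class outcome")
    X = build_design(d, age_col, covariates)
    aliased = _aliased_columns(X)
    if aliased:
        raise np.linalg.LinAlgError(f"rank-deficient design; aliased: {aliased}")
    if detect_separation(y.to_numpy(), X.to_numpy()):
        raise SeparationError(f"cohort {cohort or '?'}: separated design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0)
    ci = res.conf_int().loc["age"]
    return _binary_result(
        outcome, cohort, stage, "logistic", int(res.nobs),
        res.params["age"], (ci[0], ci[1]), res.pvalues["age"], covariates,
    )


def fit_firth(
    data: pd.DataFrame,
    outcome: str,
    covariates=(),
    age_col: str = "age",
    cohort: str = "",
    stage: str = "screen",
) -> AssociationResult:
    """Firth-penalized logistic fit (finite under separation)."""
    d = _complete_cases(data, outcome, age_col, covariates)
    y = d[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"cohort {cohort or '?'}: single-class outcome")
    X = build_design(d, age_col, covariates)
    aliased = _aliased_columns(X)
    if aliased:
        raise np.linalg.LinAlgError(f"rank-deficient design; aliased: {aliased}")
    model = FirthLogit(y.to_numpy(), X.to_numpy(), exog_names=list(X.columns))
    res = model.fit()
    j = list(X.columns).index("age")
    ci = res.conf_int()[j]
    return _binary_result(
        outcome, cohort, stage, "firth", res.nobs,
        res.params[j], (ci[0], ci[1]), res.pvalues[j], covariates,
    )


def _fit_binary_with_fallback(data, outcome, covariates, cohort, stage):
    try:
        return fit_logistic(data, outcome, covariates, cohort=cohort, stage=stage)
    except (SeparationError, ConvergenceError, np.linalg.LinAlgError):
        return fit_firth(data, outcome, covariates, cohort=cohort, stage=stage)


class AgeAssociationCascade:
    """Screen-then-adjust age-association model over cancer-type cohorts.

    Stage 1 fits the simple (age-only) model within each cohort and
    BH-corrects across cohorts; cohorts passing adj_p < alpha proceed to
    stage 2, a multiple regression with the selected clinical covariates
    plus tumour purity.

    Parameters
    ----------
    data : per-sample table holding the outcome, 'age', the cohort
        column and the covariate candidates.
    outcome : outcome column name.
    kind : 'continuous' (OLS) or 'binary' (logistic with Firth fallback).
    covariate_candidates : clinical columns considered at stage 2.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        kind: str = "continuous",
        cohort_col: str = "cancer_type",
        covariate_candidates=("gender", "race", "stage", "grade", "smoking", "alcohol"),
        purity_col: str | None = "purity",
        alpha: float = ALPHA_DEFAULT,
        max_missing: float = MAX_MISSING_DEFAULT,
    ):
        if kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {kind!r}")
        if cohort_col not in data.columns:
            raise ValueError(f"cohort column {cohort_col!r} absent")
        self.data = data
        self.outcome = outcome
        self.kind = kind
        self.cohort_col = cohort_col
        self.covariate_candidates = list(covariate_candidates)
        self.purity_col = purity_col
        self.alpha = alpha
        self.max_missing = max_missing

    @classmethod
    def from_dataframe(cls, outcome_values: pd.Series, clinical: pd.DataFrame, **kw):
        """Build from a sample-indexed outcome series plus a clinical table."""
        data = clinical.set_index("sample_id").join(
            outcome_values.rename("_outcome"), how="inner"
        )
        return cls(data.reset_index(), outcome="_outcome", **kw)

    def _fit_one(self, cohort_data, covariates, cohort, stage):
        if self.kind == "continuous":
            fitter = fit_linear
        else:
            fitter = _fit_binary_with_fallback
            if stage == "screen":
                return _fit_binary_with_fallback(
                    cohort_data, self.outcome, covariates, cohort, stage
                )
        return fitter(cohort_data, self.outcome, covariates, cohort=cohort, stage=stage)

    def _fit_adjusted(self, cohort_data, cohort):
        covs = (
            covariate_select(cohort_data, self.covariate_candidates, self.max_missing)
            if self.covariate_candidates
            else []
        )
        if self.purity_col and self.purity_col in cohort_data.columns:
            extra = covariate_select(cohort_data, [self.purity_col], self.max_missing)
            covs = covs + [c for c in extra if c not in covs]
        while True:
            try:
                if self.kind == "continuous":
                    return fit_linear(
                        cohort_data, self.outcome, covs, cohort=cohort, stage="adjusted"
                    )
                return _fit_binary_with_fallback(
                    cohort_data, self.outcome, covs, cohort, "adjusted"
                )
            except np.linalg.LinAlgError as err:
                # degenerate covariate: drop the offender and refit
                dropped = None
                for cov in reversed(covs):
                    if cov in str(err) or any(f"{cov}[" in t for t in str(err).split(",")):
                        dropped = cov
                        break
                if dropped is None and covs:
                    dropped = covs[-1]
                if dropped is None:
                    raise
                warnings.warn(
                    f"cohort {cohort}: dropping degenerate covariate {dropped!r}"
                )
                covs = [c for c in covs if c != dropped]

    def fit(self) -> "AgeAssociationResults":
        screen_results: list[AssociationResult] = []
        cohort_frames: dict[str, pd.DataFrame] = {}
        for cohort, grp in self.data.groupby(self.cohort_col, sort=True):
            cohort_frames[str(cohort)] = grp
            try:
                res = self._fit_one(grp, (), str(cohort), "screen")
            except (ValueError, ConvergenceError) as err:
                warnings.warn(f"cohort {cohort}: screen failed ({err})")
                continue
            res.bh_family = f"screen:{self.outcome}"
            screen_results.append(res)
        if not screen_results:
            raise ValueError("no cohort produced a screening fit")
        adj = bh_adjust([r.p for r in screen_results])
        for r, a in zip(screen_results, adj):
            r.adj_p = float(a)

        adjusted_results: list[AssociationResult] = []
        for r in screen_results:
            if r.adj_p < self.alpha:
                res2 = self._fit_adjusted(cohort_frames[r.cohort], r.cohort)
                res2.bh_family = f"adjusted:{self.outcome}"
                adjusted_results.append(res2)
        if adjusted_results:
            adj2 = bh_adjust([r.p for r in adjusted_results])
            for r, a in zip(adjusted_results, adj2):
                r.adj_p = float(a)
        return AgeAssociationResults(self, screen_results, adjusted_results)

    def fit_pan_cancer(self) -> AssociationResult:
        """Single multiple regression across all cohorts.

        Pan-cancer models always adjust for gender, race and cancer
        type (where present); the result is a single test, left
        unadjusted for multiplicity.
        """
        covs = [
            c
            for c in PAN_CANCER_COVARIATES
            if c == self.cohort_col or c in self.data.columns
        ]
        covs = [self.cohort_col if c == "cancer_type" else c for c in covs]
        covs = list(dict.fromkeys(c for c in covs if c in self.data.columns))
        covs = covariate_select(self.data, covs, max_missing=1.0)
        if self.kind == "continuous":
            res = fit_linear(
                self.data, self.outcome, covs, cohort="pan-cancer", stage="adjusted"
            )
        else:
            res = _fit_binary_with_fallback(
                self.data, self.outcome, covs, "pan-cancer", "adjusted"
            )
        res.adj_p = res.p
        res.bh_family = "pan-cancer:single-test"
        return res


class AgeAssociationResults:
    """Fitted cascade: stage tables, screened-in cohorts, summary."""

    def __init__(self, model, screen_results, adjusted_results):
        self.model = model
        self.screen_results = screen_results
        self.adjusted_results = adjusted_results

    @property
    def table(self) -> pd.DataFrame:
        rows = [r.to_row() for r in self.screen_results + self.adjusted_results]
        return pd.DataFrame(rows)

    @property
    def screened_in(self) -> list[str]:
        return [r.cohort for r in self.screen_results if r.adj_p < self.model.alpha]

    def summary(self) -> str:
        lines = [
            f"Age-association cascade: outcome={self.model.outcome!r} "
            f"({self.model.kind}), {len(self.screen_results)} cohorts screened, "
            f"{len(self.adjusted_results)} adjusted",
        ]
        with pd.option_context("display.width", 140, "display.max_columns", 20):
            lines.append(self.table.drop(columns="covariates").to_string(index=False))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# nonparametric group tests


@dataclass
class GroupTestResult:
    """Kruskal-Wallis + Dunn post-hoc (+ rank-sum for two groups)."""

    kruskal_h: float
    kruskal_p: float
    p_source: str  # chi2 | exact
    dunn: pd.DataFrame
    wilcoxon_p: float | None = None
    group_sizes: dict = field(default_factory=dict)


def _kruskal_h(ranks_by_group, n_total, tie_term) -> float:
    num = 12.0 / (n_total * (n_total + 1)) * sum(
        r.sum() ** 2 / len(r) for r in ranks_by_group
    ) - 3 * (n_total + 1)
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:
        return 0.0
    return num / correction


def _exact_kw_p(ranks: np.ndarray, sizes: list[int], h_obs: float, tie_term) -> float:
    """Exact permutation p by enumerating group assignments of the ranks."""
    n = len(ranks)
    idx = tuple(range(n))
    count = 0
    total = 0

    def recurse(remaining: tuple, sizes_left: list[int], groups: list[np.ndarray]):
        nonlocal count, total
        if not sizes_left:
            h = _kruskal_h(groups, n, tie_term)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        k = sizes_left[0]
        for members in itertools.combinations(remaining, k):
            left = tuple(i for i in remaining if i not in set(members))
            recurse(left, sizes_left[1:], groups + [ranks[list(members)]])

    recurse(idx, sizes, [])
    return count / total


def rank_group_tests(
    values,
    group_labels,
    exact_max_n: int = 10,
    bonferroni: bool = True,
) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis with Dunn's post-hoc comparisons.

    The Kruskal-Wallis p uses the chi-square approximation except for
    tiny samples (total n <= ``exact_max_n``), where the exact
    permutation distribution of H is enumerated.  Dunn z statistics use
    pooled ranks with tie correction; pairwise p values are two-sided
    normal, Bonferroni-multiplied.  With exactly two groups the
    two-sided Wilcoxon rank-sum p is reported as well.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if len(values) != len(labels):
        raise ValueError("values/labels length mismatch")
    group_names = [str(g) for g in pd.unique(labels)]
    groups = {g: values[labels == g] for g in group_names}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")

    n_total = len(values)
    ranks = stats.rankdata(values, method="average")
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    ranks_by_group = [ranks[labels == g] for g in group_names]
    h = _kruskal_h(ranks_by_group, n_total, tie_term)

    if np.all(values == values[0]):
        kw_p, source = 1.0, "degenerate"
        h = 0.0
    elif n_total <= exact_max_n:
        sizes = [len(groups[g]) for g in group_names]
        kw_p = _exact_kw_p(ranks, sizes, h, tie_term)
        source = "exact"
    else:
        kw_p = float(stats.chi2.sf(h, df=len(groups) - 1))
        source = "chi2"

    # Dunn pairwise z on pooled ranks
    sigma_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(group_names, 2))
    rows = []
    for g1, g2 in pairs:
        r1 = ranks[labels == g1]
        r2 = ranks[labels == g2]
        se = np.sqrt(sigma_base * (1.0 / len(r1) + 1.0 / len(r2)))
        z = (r1.mean() - r2.mean()) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((g1, g2, float(z), float(p)))
    dunn = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    if bonferroni:
        dunn["adj_p"] = np.minimum(dunn["p"] * len(pairs), 1.0)

    wilcoxon_p = None
    if len(groups) == 2 and not np.all(values == values[0]):
        g1, g2 = group_names
        wilcoxon_p = float(
            stats.mannwhitneyu(groups[g1], groups[g2], alternative="two-sided").pvalue
        )
    return GroupTestResult(
        kruskal_h=float(h),
        kruskal_p=float(kw_p),
        p_source=source,
        dunn=dunn,
        wilcoxon_p=wilcoxon_p,
        group_sizes={g: int(len(v)) for g, v in groups.items()},
    )
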
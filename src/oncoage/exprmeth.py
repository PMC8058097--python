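"""Coupled expression/methylation age analysis.

Expression is filtered to genes detected (RSEM > 0) in strictly more
than half the samples, log2(x+1)-transformed, and regressed per gene on
age with clinical covariates; genes at BH-adjusted p < 0.05 are
age-DEGs.  Methylation beta values are collapsed probe->gene by keeping,
for each gene, the probe most negatively correlated with that gene's
expression, then regressed the same way (age-DMGs).  Overlap genes are
classified into the four sign quadrants, and per-gene methylation-
expression correlations are compared across the DMG/DEG partition with
Kruskal-Wallis and Dunn tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust, build_design, rank_group_tests
from .containers import OmicsMatrix

FLAG_ALPHA = 0.05
MIN_SHARED_SAMPLES = 3

GROUP_BOTH = "age-DMGs-DEGs"
GROUP_DMG = "age-DMGs"
GROUP_DEG = "age-DEGs"
GROUP_OTHER = "others"

QUADRANTS = ("meth_down_expr_down", "meth_down_expr_up",
             "meth_up_expr_down", "meth_up_expr_up")
OPPOSITE_QUADRANTS = ("meth_up_expr_down", "meth_down_expr_up")


def filter_expressed(expr: OmicsMatrix, min_fraction: float = 0.5) -> OmicsMatrix:
    """Keep genes with RSEM > 0 in strictly more than ``min_fraction`` of samples."""
    if expr.kind != "expression":
        raise ValueError("filter_expressed expects an expression matrix")
    frac = (expr.values > 0).sum(axis=1) / expr.values.shape[1]
    return OmicsMatrix(
        values=expr.values[frac > min_fraction],
        kind="expression",
        log_transformed=expr.log_transformed,
    )


def log2_expr(expr: OmicsMatrix) -> OmicsMatrix:
    """log2(RSEM + 1), applied uniformly."""
    if (expr.values.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return OmicsMatrix(
        values=np.log2(expr.values + 1.0), kind="expression", log_transformed=True
    )


def map_probes(
    meth: OmicsMatrix,
    probe_map: pd.DataFrame,
    log_expr: OmicsMatrix,
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Collapse a probe matrix to gene level by the most-negative-r rule.

    For each gene, the probe whose beta values correlate most negatively
    (Pearson, over shared samples) with the gene's log2 expression is
    selected; ties break to the lexicographically smallest probe ID, so
    the mapping is invariant to probe input order.  Returns the
    gene-level matrix and the one-to-one gene->probe mapping.
    """
    shared = meth.samples.intersection(log_expr.samples)
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValueError("no (or too few) shared samples between matrices")
    chosen: list[tuple[str, str, float]] = []
    by_gene = probe_map.groupby("gene")["probe"]
    for gene, probes in by_gene:
        if gene not in log_expr.features.values:
            continue
        e = log_expr.values.loc[gene, shared].to_numpy(dtype=float)
        best: tuple[float, str] | None = None
        for probe in sorted(probes):
            if probe not in meth.features.values:
                continue
            b = meth.values.loc[probe, shared].to_numpy(dtype=float)
            ok = np.isfinite(b) & np.isfinite(e)
            if ok.sum() < MIN_SHARED_SAMPLES:
                continue
            if np.std(b[ok]) == 0 or np.std(e[ok]) == 0:
                continue
            r = float(stats.pearsonr(b[ok], e[ok]).statistic)
            if best is None or r < best[0] - 1e-15:
                best = (r, probe)
        if best is not None:
            chosen.append((gene, best[1], best[0]))
    if not chosen:
        raise ValueError("no gene received a probe")
    mapping = pd.DataFrame(chosen, columns=["gene", "probe", "pearson_r"])
    gene_meth = meth.values.loc[mapping["probe"]].copy()
    gene_meth.index = mapping["gene"].values
    return OmicsMatrix(values=gene_meth, kind="methylation"), mapping


def age_feature_regression(
    matrix: OmicsMatrix,
    clinical: pd.DataFrame,
    covariates=(),
    platform: pd.Series | None = None,
    alpha: float = FLAG_ALPHA,
) -> pd.DataFrame:
    """Per-feature OLS of value on age + covariates, BH across features.

    ``clinical`` must carry sample_id and age; covariates are assumed
    pre-selected (see ``covariate_select``).  ``platform`` optionally
    adds a per-sample platform covariate.  Zero-variance features are
    skipped and excluded from the BH family.  Returns one row per
    retained feature: coefficient (per-year), p, adj_p, flag, direction.
    """
    clin = clinical.set_index("sample_id")
    if platform is not None:
        clin = clin.join(platform.rename("platform"), how="left")
        covariates = list(covariates) + ["platform"]
    cols = ["age", *covariates]
    clin = clin[cols].dropna()
    shared = matrix.samples.intersection(clin.index)
    if len(shared) < len(cols) + 2:
        raise ValueError("too few complete-case samples for regression")
    clin = clin.loc[shared]
    X = build_design(clin, "age", covariates).to_numpy(dtype=float)
    age_idx = 1  # const, age, ...
    n, p_dim = X.shape
    Y = matrix.values[shared].to_numpy(dtype=float).T  # n x G
    features = matrix.features.to_numpy()

    coefs = np.full(len(features), np.nan)
    pvals = np.full(len(features), np.nan)
    has_nan = np.isnan(Y).any(axis=0)
    variable = np.nanstd(Y, axis=0) > 0

    # vectorised fit for complete features
    full = ~has_nan & variable
    if full.any():
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Y[:, full]
        resid = Y[:, full] - X @ B
        dof = n - p_dim
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * XtX_inv[age_idx, age_idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = B[age_idx] / se
        coefs[full] = B[age_idx]
        pvals[full] = 2.0 * stats.t.sf(np.abs(t), dof)

    # per-feature complete-case fits where values are missing
    for j in np.where(has_nan & variable)[0]:
        y = Y[:, j]
        ok = np.isfinite(y)
        if ok.sum() <= p_dim + 1 or np.std(y[ok]) == 0:
            continue
        Xj = X[ok]
        XtX_inv = np.linalg.pinv(Xj.T @ Xj)
        b = XtX_inv @ Xj.T @ y[ok]
        resid = y[ok] - Xj @ b
        dof = ok.sum() - p_dim
        sigma2 = (resid**2).sum() / dof
        se = np.sqrt(sigma2 * XtX_inv[age_idx, age_idx])
        if se == 0:
            continue
        coefs[j] = b[age_idx]
        pvals[j] = 2.0 * stats.t.sf(abs(b[age_idx] / se), dof)

    keep = np.isfinite(pvals)
    out = pd.DataFrame(
        {"feature": features[keep], "coefficient": coefs[keep], "p": pvals[keep]}
    )
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["flag"] = out["adj_p"] < alpha
    out["direction"] = np.where(out["coefficient"] >= 0, "up", "down")
    return out.set_index("feature")


@dataclass
class OverlapClassification:
    """Quadrant counts for DMG/DEG overlap genes and the group partition."""

    quadrants: pd.Series  # overlap gene -> quadrant label
    quadrant_counts: dict
    opposite_pct: float  # percent of overlap genes with opposite directions
    groups: pd.Series  # universe gene -> group label

    @property
    def n_overlap(self) -> int:
        return len(self.quadrants)


def classify_overlap(
    expr_results: pd.DataFrame, meth_results: pd.DataFrame
) -> OverlapClassification:
    """Assign DMG∩DEG genes to sign quadrants and partition the universe."""
    universe = expr_results.index.union(meth_results.index)
    deg = set(expr_results.index[expr_results["flag"]])
    dmg = set(meth_results.index[meth_results["flag"]])
    overlap = sorted(deg & dmg)
    quad = {}
    for gene in overlap:
        m = "up" if meth_results.loc[gene, "direction"] == "up" else "down"
        e = "up" if expr_results.loc[gene, "direction"] == "up" else "down"
        quad[gene] = f"meth_{m}_expr_{e}"
    quadrants = pd.Series(quad, dtype=object)
    counts = {q: int((quadrants == q).sum()) for q in QUADRANTS}
    n_opp = sum(counts[q] for q in OPPOSITE_QUADRANTS)
    opposite_pct = 100.0 * n_opp / len(overlap) if overlap else np.nan

    def group_of(gene):
        if gene in dmg and gene in deg:
            return GROUP_BOTH
        if gene in dmg:
            return GROUP_DMG
        if gene in deg:
            return GROUP_DEG
        return GROUP_OTHER

    groups = pd.Series({g: group_of(g) for g in universe}, dtype=object)
    return OverlapClassification(
        quadrants=quadrants,
        quadrant_counts=counts,
        opposite_pct=opposite_pct,
        groups=groups,
    )


def gene_meth_expr_correlation(
    log_expr: OmicsMatrix, gene_meth: OmicsMatrix
) -> pd.Series:
    """Per-gene Pearson r of beta vs log2 expression (complete cases)."""
    shared = log_expr.samples.intersection(gene_meth.samples)
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValueError("too few shared samples")
    genes = log_expr.features.intersection(gene_meth.features)
    out = {}
    for gene in genes:
        e = log_expr.values.loc[gene, shared].to_numpy(dtype=float)
        b = gene_meth.values.loc[gene, shared].to_numpy(dtype=float)
        ok = np.isfinite(e) & np.isfinite(b)
        if ok.sum() < MIN_SHARED_SAMPLES or np.std(e[ok]) == 0 or np.std(b[ok]) == 0:
            continue
        out[gene] = float(stats.pearsonr(b[ok], e[ok]).statistic)
    return pd.Series(out, name="pearson_r")


def correlation_groups(
    log_expr: OmicsMatrix,
    gene_meth: OmicsMatrix,
    expr_results: pd.DataFrame,
    meth_results: pd.DataFrame,
):
    """Compare meth-expr correlations across the DMG/DEG groups.

    Returns (per-gene table with r and group, rank_group_tests result).
    """
    overlap = classify_overlap(expr_results, meth_results)
    r = gene_meth_expr_correlation(log_expr, gene_meth)
    table = pd.DataFrame({"pearson_r": r})
    table["group"] = overlap.groups.reindex(table.index)
    table = table.dropna()
    tests = rank_group_tests(table["pearson_r"].to_numpy(), table["group"].to_numpy())
    return table, tests


def coefficient_concordance(
    expr_results: pd.DataFrame, meth_results: pd.DataFrame
) -> tuple[float, float]:
    """Pearson r (and p) between per-gene age coefficients of the two layers."""
    genes = expr_results.index.intersection(meth_results.index)
    if len(genes) < MIN_SHARED_SAMPLES:
        raise ValueError("too few shared genes")
    x = expr_results.loc[genes, "coefficient"].to_numpy(dtype=float)
    y = meth_results.loc[genes, "coefficient"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def make_ranked_list(results: pd.DataFrame) -> pd.DataFrame:
    """Features sorted by age coefficient, descending; ties by feature ID.

    The two-column output feeds external rank-based enrichment tools.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    out = results.reset_index()[["feature", "coefficient"]]
    out = out.sort_values(
        ["coefficient", "feature"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
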
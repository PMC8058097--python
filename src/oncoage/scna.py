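"""SCNA event classification and hierarchical SCNA scores.

Each GISTIC-style log2 copy-number ratio is binned into an integer class
score in {-2, -1, 0, 1, 2}; per-tumour |class| sums at focal, arm and
chromosome level are rank-normalised (average rank / cohort size) within
each cancer-type cohort; the overall score is the sum of the three
normalised levels and the chromosome/arm score the sum of the broad two.

A broad event counts as chromosome-level when both arms of a chromosome
carry the same log2 ratio (within a small tolerance), otherwise each arm
is an arm-level event; single-arm (acrocentric) chromosomes always emit
arm-level events.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .genome import ArmModel

CLASS_EDGES_DOC = "2: log2>=1; 1: [0.25,1); 0: [-0.25,0.25); -1: [-1,-0.25); -2: <-1"
SAME_RATIO_TOL = 1e-9
TELOMERE_WINDOW_DEFAULT = 10_000


def classify_log2(ratio: float) -> int:
    """Classify one log2 copy-number ratio into the five-band class score."""
    if not math.isfinite(ratio):
        raise ValueError(f"non-finite log2 ratio: {ratio}")
    if ratio >= 1:
        return 2
    if ratio >= 0.25:
        return 1
    if ratio >= -0.25:
        return 0
    if ratio >= -1:
        return -1
    return -2


def split_broad_events(
    arm_values: dict[str, float],
    arm_model: ArmModel,
    tol: float = SAME_RATIO_TOL,
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Split one sample's arm->log2 map into chromosome and arm events.

    Returns (chromosome_events, arm_events) as (locus, log2) pairs.
    """
    by_chrom: dict[str, dict[str, float]] = {}
    for label, value in arm_values.items():
        chrom, arm = arm_model.validate_arm(label)
        by_chrom.setdefault(chrom, {})[arm] = float(value)
    chrom_events: list[tuple[str, float]] = []
    arm_events: list[tuple[str, float]] = []
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        arms = by_chrom[chrom]
        if len(arms) == 2 and abs(arms["p"] - arms["q"]) <= tol:
            chrom_events.append((chrom, arms["p"]))
        else:
            for arm in sorted(arms):
                arm_events.append((f"{chrom}{arm}", arms[arm]))
    return chrom_events, arm_events


def raw_level_score(log2_ratios) -> int:
    """Sum of |class score| over one sample's events at one level."""
    return int(sum(abs(classify_log2(r)) for r in log2_ratios))


def rank_normalize(raw_scores: pd.Series) -> pd.Series:
    """Average rank / cohort size, within one cancer-type cohort."""
    if len(raw_scores) == 0:
        raise ValueError("empty cohort")
    ranks = stats.rankdata(raw_scores.to_numpy(), method="average")
    return pd.Series(ranks / len(raw_scores), index=raw_scores.index)


def scna_scores(
    broad: pd.DataFrame,
    focal: pd.DataFrame,
    cohorts: pd.Series,
    arm_model: ArmModel,
    tol: float = SAME_RATIO_TOL,
) -> pd.DataFrame:
    """Per-sample hierarchical SCNA scores.

    Parameters
    ----------
    broad : arms x samples log2 matrix (GISTIC broad_values_by_arm layout).
    focal : long table with columns sample, log2_ratio (one row per lesion).
    cohorts : sample -> cancer-type label; every scored sample must appear.
    """
    samples = list(cohorts.index)
    extra = (set(broad.columns) | set(focal["sample"])) - set(samples)
    if extra:
        raise ValueError(f"samples missing from cohort assignment: {sorted(extra)[:5]}")

    focal_raw = pd.Series(0, index=samples, dtype=int)
    for sample, grp in focal.groupby("sample"):
        focal_raw[sample] = raw_level_score(grp["log2_ratio"])

    arm_raw = pd.Series(0, index=samples, dtype=int)
    chrom_raw = pd.Series(0, index=samples, dtype=int)
    for sample in broad.columns:
        col = broad[sample].dropna()
        chrom_ev, arm_ev = split_broad_events(col.to_dict(), arm_model, tol=tol)
        chrom_raw[sample] = raw_level_score([v for _, v in chrom_ev])
        arm_raw[sample] = raw_level_score([v for _, v in arm_ev])

    out = pd.DataFrame(
        {
            "sample": samples,
            "cancer_type": cohorts.values,
            "focal_raw": focal_raw.values,
            "arm_raw": arm_raw.values,
            "chrom_raw": chrom_raw.values,
        }
    ).set_index("sample")
    for level in ("focal", "arm", "chrom"):
        out[f"{level}_norm"] = np.nan
    for _, idx in out.groupby("cancer_type").groups.items():
        for level in ("focal", "arm", "chrom"):
            out.loc[idx, f"{level}_norm"] = rank_normalize(out.loc[idx, f"{level}_raw"])
    out["chrom_arm"] = out["arm_norm"] + out["chrom_norm"]
    out["overall"] = out["focal_norm"] + out["chrom_arm"]
    return out.reset_index()


def filter_focal_regions(
    regions: pd.DataFrame,
    arm_model: ArmModel,
    telomere_window: int = TELOMERE_WINDOW_DEFAULT,
) -> pd.DataFrame:
    """Drop focal regions overlapping a centromere or telomere window.

    Input coordinates are 1-based inclusive; overlap tests run on
    half-open intervals after conversion, so a region ending exactly at
    a window boundary is kept.  Telomere windows are the first and last
    ``telomere_window`` bases of each chromosome.
    """
    keep = []
    for row in regions.itertuples(index=False):
        chrom = arm_model[row.chromosome]
        if row.start < 1 or row.end > chrom.length:
            raise ValueError(
                f"region {getattr(row, 'region', '?')} outside chromosome "
                f"{row.chromosome}"
            )
        # half-open [start-1, end)
        lo, hi = row.start - 1, row.end
        windows = [
            (chrom.cen_start - 1, chrom.cen_end),
            (0, telomere_window),
            (chrom.length - telomere_window, chrom.length),
        ]
        overlaps = any(lo < w_hi and w_lo < hi for w_lo, w_hi in windows)
        keep.append(not overlaps)
    return regions[pd.Series(keep, index=regions.index)].copy()


def scna_expr_correlation(
    gene_scores: pd.DataFrame,
    log_expression: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of gene-level SCNA with log2 expression.

    Both inputs are gene x sample; expression must already be
    log2(RSEM + 1).  Genes with zero variance in either vector are
    flagged undefined and excluded from the BH family.
    """
    shared_samples = gene_scores.columns.intersection(log_expression.columns)
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 shared samples for correlation")
    genes = gene_scores.index.intersection(log_expression.index)
    rows = []
    for gene in genes:
        x = gene_scores.loc[gene, shared_samples].to_numpy(dtype=float)
        y = log_expression.loc[gene, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append((gene, np.nan, np.nan, True, int(ok.sum())))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((gene, float(r), float(p), False, int(ok.sum())))
    out = pd.DataFrame(
        rows, columns=["gene", "pearson_r", "p", "undefined", "n"]
    ).set_index("gene")
    out["adj_p"] = np.nan
    defined = ~out["undefined"]
    if defined.any():
        out.loc[defined, "adj_p"] = bh_adjust(out.loc[defined, "p"].to_numpy())
    return out.reset_index()
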
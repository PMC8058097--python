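"""Mutation burden, substitution classes and hypermutation statistics.

Burden counts non-silent variants per exome; a tumour is hypermutated
when it exceeds 1000 non-silent mutations, and gene-level analyses are
restricted to tumours strictly below 1000 (and non-MSI-H).  Substitution
spectra collapse purine-reference SNVs onto the six pyrimidine-reference
classes C>A, C>G, C>T, T>A, T>C, T>G.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MutationTable

NONSILENT_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

HYPERMUTATION_THRESHOLD = 1000  # strictly greater-than
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
YOUNG_AGE_MAX = 50  # young: age <= 50; old: age > 50


def filter_nonsilent(table: MutationTable) -> MutationTable:
    """Keep only the nine non-silent Variant_Classification values."""
    keep = table.records["Variant_Classification"].isin(NONSILENT_CLASSES)
    return MutationTable(records=table.records[keep].reset_index(drop=True))


def mutation_burden(table: MutationTable, samples=None) -> pd.DataFrame:
    """Per-sample non-silent burden and log10(burden + 1).

    ``samples`` optionally fixes the output universe so zero-burden
    samples appear with burden 0.  The table must already be
    non-silent-filtered.
    """
    counts = table.records.groupby("Tumor_Sample_Barcode").size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    out = pd.DataFrame({"sample": counts.index.astype(str), "burden": counts.values})
    out["log_burden"] = np.log10(out["burden"] + 1)
    out["hypermutated"] = out["burden"] > HYPERMUTATION_THRESHOLD
    return out.reset_index(drop=True)


def hypermutation_flag(burden: int) -> bool:
    """Hypermutated iff strictly more than 1000 non-silent mutations."""
    if burden < 0:
        raise ValueError("negative burden")
    return burden > HYPERMUTATION_THRESHOLD


def _collapse(ref: str, alt: str) -> str | None:
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    return cls if cls in SUBSTITUTION_CLASSES else None


def substitution_fractions(table: MutationTable) -> pd.DataFrame:
    """Six pyrimidine-reference substitution fractions per sample.

    Only single-base SNVs with ref != alt contribute; indels and
    multi-base records are skipped with a warning.  Fractions sum to 1
    for every sample with at least one usable SNV.
    """
    rec = table.records
    snv = rec[
        (rec["Reference_Allele"].str.len() == 1)
        & (rec["Tumor_Seq_Allele2"].str.len() == 1)
        & rec["Reference_Allele"].isin(list("ACGT"))
        & rec["Tumor_Seq_Allele2"].isin(list("ACGT"))
    ]
    if (snv["Reference_Allele"] == snv["Tumor_Seq_Allele2"]).any():
        raise ValueError("SNV record with reference allele equal to alt allele")
    skipped = len(rec) - len(snv) - (rec["Variant_Type"] != "SNP").sum()
    if skipped > 0:
        warnings.warn(f"{skipped} malformed SNV records skipped from spectra")
    classes = [
        _collapse(r, a)
        for r, a in zip(snv["Reference_Allele"], snv["Tumor_Seq_Allele2"])
    ]
    snv = snv.assign(sub_class=classes)
    counts = (
        snv.groupby(["Tumor_Sample_Barcode", "sub_class"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=SUBSTITUTION_CLASSES, fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions.index.name = "sample"
    return fractions.reset_index()


def gene_mutation_matrix(
    table: MutationTable,
    cohort_samples,
    min_frequency: float = 0.05,
) -> pd.DataFrame:
    """Binary gene x sample matrix over an already-restricted cohort.

    The caller restricts ``cohort_samples`` to non-hypermutated
    (<1000 mutations), non-MSI-H tumours; variants from samples outside
    the cohort are ignored.  Genes mutated in strictly more than
    ``min_frequency`` of cohort samples are retained.
    """
    cohort_samples = list(cohort_samples)
    if not cohort_samples:
        raise ValueError("empty cohort")
    rec = table.records[table.records["Tumor_Sample_Barcode"].isin(cohort_samples)]
    mat = (
        rec.groupby(["Hugo_Symbol", "Tumor_Sample_Barcode"])
        .size()
        .gt(0)
        .astype(int)
        .unstack(fill_value=0)
        .reindex(columns=cohort_samples, fill_value=0)
    )
    freq = mat.sum(axis=1) / len(cohort_samples)
    mat = mat[freq > min_frequency]
    mat.index.name = "gene"
    return mat


def age_group_split(ages: pd.Series) -> pd.Series:
    """'young' (age <= 50) vs 'old' (age > 50); missing ages excluded."""
    ages = pd.to_numeric(ages, errors="coerce")
    if ages.isna().any():
        warnings.warn(f"{int(ages.isna().sum())} samples with missing age excluded")
        ages = ages.dropna()
    return pd.Series(
        np.where(ages <= YOUNG_AGE_MAX, "young", "old"), index=ages.index
    )


def hypermutation_enrichment(
    hyper_flags: pd.Series, age_groups: pd.Series
) -> dict:
    """Hypermutation proportions by age group with two-sided Fisher p.

    Returns the 2x2 table [[young_hyper, young_other],
    [old_hyper, old_other]], the group percentages and Fisher's exact p.
    """
    shared = hyper_flags.index.intersection(age_groups.index)
    flags = hyper_flags.loc[shared].astype(bool)
    groups = age_groups.loc[shared]
    n_young = int((groups == "young").sum())
    n_old = int((groups == "old").sum())
    young_hyper = int(flags[groups == "young"].sum())
    old_hyper = int(flags[groups == "old"].sum())
    table = [[young_hyper, n_young - young_hyper], [old_hyper, n_old - old_hyper]]
    out = {
        "table": table,
        "young_pct": 100.0 * young_hyper / n_young if n_young else np.nan,
        "old_pct": 100.0 * old_hyper / n_old if n_old else np.nan,
        "undefined": n_young == 0 or n_old == 0,
    }
    out["fisher_p"] = (
        float(stats.fisher_exact(table, alternative="two-sided").pvalue)
        if not out["undefined"]
        else np.nan
    )
    return out


def contingency_summary(young_hyper, n_young, old_hyper, n_old) -> dict:
    """Enrichment summary straight from printed contingency counts."""
    flags = pd.Series(
        [True] * young_hyper
        + [False] * (n_young - young_hyper)
        + [True] * old_hyper
        + [False] * (n_old - old_hyper)
    )
    groups = pd.Series(["young"] * n_young + ["old"] * n_old)
    return hypermutation_enrichment(flags, groups)
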
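"""In-memory containers shared across the pipeline.

Segment, mutation and omics tables are held as pandas DataFrames inside
thin dataclasses that pin down the schema and the validated invariants;
clinical tables stay plain DataFrames with a checked schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import VALID_CHROMOSOMES

SEGMENT_COLUMNS = ["chromosome", "start", "end", "n_major", "n_minor"]
MAF_COLUMNS = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
]


class SchemaError(ValueError):
    """A required column is absent or mistyped."""


class ValidationError(ValueError):
    """Values violate a documented invariant."""


@dataclass
class SegmentProfile:
    """One tumour's allele-specific copy-number segments.

    ``segments`` holds 1-based inclusive coordinates with integer major
    and minor allele copy numbers (major >= minor >= 0).  ``ploidy``,
    ``purity`` and ``wgd`` may be supplied from an upstream caller or
    derived by :mod:`oncoage.instability`.
    """

    sample_id: str
    segments: pd.DataFrame
    ploidy: float | None = None
    purity: float | None = None
    wgd: bool | None = None

    def __post_init__(self):
        missing = [c for c in SEGMENT_COLUMNS if c not in self.segments.columns]
        if missing:
            raise SchemaError(f"segment table missing columns: {missing}")
        seg = self.segments[SEGMENT_COLUMNS]
        if seg["chromosome"].dtype != object:
            seg = seg.assign(chromosome=seg["chromosome"].astype(str))
        for col in ("start", "end", "n_major", "n_minor"):
            if seg[col].dtype != np.int64:
                seg = seg.assign(**{col: seg[col].astype(np.int64)})
        chrom = seg["chromosome"].to_numpy()
        start = seg["start"].to_numpy()
        if not (
            (chrom[1:] >= chrom[:-1]).all()
            and ((chrom[1:] != chrom[:-1]) | (start[1:] >= start[:-1])).all()
        ):
            seg = seg.sort_values(["chromosome", "start"], kind="mergesort")
        self.segments = seg.reset_index(drop=True)
        self._autosomal_cache: pd.DataFrame | None = None
        self._validate()

    def _validate(self) -> None:
        seg = self.segments
        chrom = seg["chromosome"].to_numpy()
        start = seg["start"].to_numpy()
        end = seg["end"].to_numpy()
        bad_chrom = set(chrom) - set(VALID_CHROMOSOMES)
        if bad_chrom:
            raise ValidationError(
                f"sample {self.sample_id}: unknown chromosomes {sorted(bad_chrom)}"
            )
        if (end < start).any():
            raise ValidationError(f"sample {self.sample_id}: segment with end < start")
        nmaj = seg["n_major"].to_numpy()
        nmin = seg["n_minor"].to_numpy()
        if (nmaj < 0).any() or (nmin < 0).any():
            raise ValidationError(f"sample {self.sample_id}: negative copy number")
        if (nmaj < nmin).any():
            raise ValidationError(
                f"sample {self.sample_id}: n_major < n_minor (alleles unsorted)"
            )
        # rows are sorted by (chromosome, start): overlap shows up adjacently
        same = chrom[1:] == chrom[:-1]
        overlap = same & (start[1:] <= end[:-1])
        if overlap.any():
            where = chrom[1:][overlap][0]
            raise ValidationError(
                f"sample {self.sample_id}: overlapping segments on "
                f"chromosome {where}"
            )

    @property
    def autosomal(self) -> pd.DataFrame:
        if self._autosomal_cache is None:
            mask = ~self.segments["chromosome"].isin(("X", "Y")).to_numpy()
            self._autosomal_cache = self.segments[mask]
        return self._autosomal_cache

    def lengths(self, seg: pd.DataFrame | None = None) -> np.ndarray:
        seg = self.segments if seg is None else seg
        return (seg["end"] - seg["start"] + 1).to_numpy()


@dataclass
class MutationTable:
    """Per-variant records with MAF column names.

    Carries the five mandatory MAF fields plus a derived ``Variant_Type``
    (SNP/INS/DEL) when ref/alt lengths allow it.
    """

    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MAF_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"MAF table missing columns: {missing}")
        rec = self.records[MAF_COLUMNS].copy()
        for col in MAF_COLUMNS:
            if rec[col].dtype != object:
                rec[col] = rec[col].astype(str)
        if "Variant_Type" in self.records.columns:
            rec["Variant_Type"] = self.records["Variant_Type"].astype(str)
        else:
            rec["Variant_Type"] = _infer_variant_type(rec)
        self.records = rec.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["Tumor_Sample_Barcode"].unique())


def _infer_variant_type(rec: pd.DataFrame) -> pd.Series:
    ref = rec["Reference_Allele"]
    alt = rec["Tumor_Seq_Allele2"]
    out = pd.Series("OTHER", index=rec.index)
    out[(ref.str.len() == 1) & (alt.str.len() == 1) & (ref != "-") & (alt != "-")] = "SNP"
    out[(ref == "-") | (alt.str.len() > ref.str.len())] = "INS"
    out[(alt == "-") | (ref.str.len() > alt.str.len())] = "DEL"
    return out


@dataclass
class OmicsMatrix:
    """Feature-by-sample matrix of expression (RSEM >= 0) or methylation beta.

    ``kind`` is 'expression' or 'methylation'; invariants are enforced on
    construction (non-negative RSEM, beta in [0, 1], unique feature IDs).
    NaNs are permitted and treated as missing downstream.
    """

    values: pd.DataFrame
    kind: str
    log_transformed: bool = field(default=False)

    def __post_init__(self):
        if self.kind not in ("expression", "methylation"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature IDs: {list(dupes[:5])}")
        vals = self.values.to_numpy(dtype=float)
        if self.kind == "methylation":
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                    raise ValidationError("methylation beta values outside [0, 1]")
        elif not self.log_transformed:
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals, initial=0.0) < 0:
                    raise ValidationError("negative expression values")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


CLINICAL_REQUIRED = ["sample_id", "age"]
CLINICAL_CATEGORICAL = [
    "cancer_type",
    "gender",
    "race",
    "stage",
    "grade",
    "smoking",
    "alcohol",
]


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Check clinical-table invariants and normalise missing markers."""
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in clinical table")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    if (df["age"] <= 0).any():
        raise ValidationError("non-positive age in clinical table")
    for col in CLINICAL_CATEGORICAL:
        if col in df.columns:
            s = df[col].astype(object)
            s = s.where(~pd.isna(s), other=np.nan)
            s = s.replace({"": np.nan, "NA": np.nan, "na": np.nan, "NaN": np.nan})
            df[col] = s
    if "purity" in df.columns:
        df["purity"] = pd.to_numeric(df["purity"], errors="coerce")
        bad = df["purity"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError("purity outside [0, 1]")
    return df
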
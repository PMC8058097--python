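"""Readers and writers for the tab-separated tables the pipeline touches.

All genomic coordinates in files are 1-based inclusive; internal length
arithmetic is ``end - start + 1``.  Every reader validates its schema and
the type invariants of the object it builds, and every writer emits a
table its reader round-trips byte-identically for valid objects.
"""

from __future__ import annotations

import pandas as pd

from .containers import (
    MAF_COLUMNS,
    MutationTable,
    OmicsMatrix,
    SchemaError,
    SegmentProfile,
    validate_clinical,
)
from .genome import ArmModel

SEG_FILE_COLUMNS = ["sample", "chromosome", "start", "end", "n_major", "n_minor"]

# aliases for SEG dialect variation (e.g. ASCAT release files)
SEG_COLUMN_ALIASES = {
    "sample": ["sample", "sample_id", "SampleID", "Sample"],
    "chromosome": ["chromosome", "chr", "Chr", "Chromosome"],
    "start": ["start", "startpos", "Start"],
    "end": ["end", "endpos", "End"],
    "n_major": ["n_major", "nMajor", "nA"],
    "n_minor": ["n_minor", "nMinor", "nB"],
}


def _resolve_columns(df: pd.DataFrame, aliases: dict[str, list[str]]) -> pd.DataFrame:
    rename = {}
    for canonical, names in aliases.items():
        found = [n for n in names if n in df.columns]
        if not found:
            raise SchemaError(f"missing column {canonical!r} (accepted: {names})")
        rename[found[0]] = canonical
    return df.rename(columns=rename)


def read_segments(
    path,
    arm_model: ArmModel | None = None,
    ploidy_purity: pd.DataFrame | None = None,
) -> list[SegmentProfile]:
    """Read a SEG-like TSV into one validated SegmentProfile per sample.

    ``ploidy_purity`` optionally supplies per-sample ploidy/purity/wgd
    columns (indexed by sample).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    df = _resolve_columns(df, SEG_COLUMN_ALIASES)
    if arm_model is not None:
        for chrom, grp in df.groupby("chromosome"):
            if chrom in arm_model:
                limit = arm_model[chrom].length
                if (grp["end"] > limit).any():
                    raise ValueError(
                        f"segment beyond chromosome {chrom} length {limit}"
                    )
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        kwargs = {}
        if ploidy_purity is not None and sample in ploidy_purity.index:
            row = ploidy_purity.loc[sample]
            for key in ("ploidy", "purity", "wgd"):
                if key in row and pd.notna(row[key]):
                    kwargs[key] = bool(row[key]) if key == "wgd" else float(row[key])
        profiles.append(
            SegmentProfile(sample_id=str(sample), segments=grp.drop(columns="sample"), **kwargs)
        )
    return profiles


def write_segments(profiles: list[SegmentProfile], path) -> None:
    frames = []
    for p in profiles:
        seg = p.segments.copy()
        seg.insert(0, "sample", p.sample_id)
        frames.append(seg)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=SEG_FILE_COLUMNS
    )
    out.to_csv(path, sep="\t", index=False)


def read_maf_minimal(path) -> MutationTable:
    """Load a MAF keeping only the five fields the pipeline consumes.

    All rows are loaded unfiltered; non-silent filtering is a separate
    operation.  Extra columns (MC3 MAFs carry ~100) are ignored.
    """
    header = pd.read_csv(path, sep="\t", nrows=0, comment="#")
    missing = [c for c in MAF_COLUMNS if c not in header.columns]
    if missing:
        raise SchemaError(f"MAF missing mandatory columns: {missing}")
    usecols = list(MAF_COLUMNS)
    if "Variant_Type" in header.columns:
        usecols.append("Variant_Type")
    df = pd.read_csv(path, sep="\t", usecols=usecols, dtype=str, comment="#")
    return MutationTable(records=df)


def write_maf(table: MutationTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_gistic_broad(path, arm_model: ArmModel) -> pd.DataFrame:
    """Read a GISTIC broad_values_by_arm-style matrix (arms x samples).

    Arm labels are validated against the arm model; acrocentric
    chromosomes may legitimately lack a p row.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for label in df.index:
        arm_model.validate_arm(label)
    if df.index.duplicated().any():
        raise ValueError("duplicate arm rows in broad matrix")
    return df.astype(float)


def write_gistic_broad(broad: pd.DataFrame, path) -> None:
    broad.to_csv(path, sep="\t", index_label="arm")


FOCAL_COLUMNS = ["sample", "region", "chromosome", "start", "end", "log2_ratio"]


def read_focal_events(path, arm_model: ArmModel | None = None) -> pd.DataFrame:
    """Read a per-sample focal lesion table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in FOCAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"focal table missing columns: {missing}")
    df = df[FOCAL_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["log2_ratio"] = df["log2_ratio"].astype(float)
    if arm_model is not None:
        for row in df.itertuples(index=False):
            if row.chromosome not in arm_model:
                raise ValueError(f"focal region on unknown chromosome {row.chromosome}")
            if row.start < 1 or row.end > arm_model[row.chromosome].length:
                raise ValueError(
                    f"focal region {row.region} outside chromosome {row.chromosome}"
                )
    return df


def write_focal_events(focal: pd.DataFrame, path) -> None:
    focal[FOCAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix(path, kind: str) -> OmicsMatrix:
    """Read a feature-by-sample matrix ('expression' or 'methylation')."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return OmicsMatrix(values=df.astype(float), kind=kind)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")


def read_probe_map(path) -> pd.DataFrame:
    """Read a probe->gene map TSV with columns probe, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("probe", "gene") if c not in df.columns]
    if missing:
        raise SchemaError(f"probe map missing columns: {missing}")
    return df[["probe", "gene"]]


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical covariate table, normalising ''/'NA' to missing."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_clinical(df)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)
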
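"""Chromosome arm models: lengths, centromeres, p/q extents.

Coordinates are 1-based inclusive throughout, matching the segment and
region tables the pipeline reads.  Acrocentric chromosomes (13, 14, 15,
21, 22 in the packaged hg19 model) carry no usable short arm: their
centromere interval is extended to position 1 so the p extent is empty
and only a q arm is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))
VALID_CHROMOSOMES = AUTOSOMES + ("X", "Y")


@dataclass(frozen=True)
class ChromosomeArms:
    """Arm geometry of one chromosome (1-based inclusive coordinates)."""

    chromosome: str
    length: int
    cen_start: int
    cen_end: int
    acrocentric: bool

    @property
    def p_extent(self) -> tuple[int, int] | None:
        """(start, end) of the p arm, or None for acrocentrics."""
        if self.acrocentric or self.cen_start <= 1:
            return None
        return (1, self.cen_start - 1)

    @property
    def q_extent(self) -> tuple[int, int]:
        return (self.cen_end + 1, self.length)

    @property
    def arm_labels(self) -> tuple[str, ...]:
        if self.p_extent is None:
            return (f"{self.chromosome}q",)
        return (f"{self.chromosome}p", f"{self.chromosome}q")

    def arm_of(self, position: int) -> str | None:
        """Arm label containing ``position``, or None if centromeric."""
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside chromosome {self.chromosome} "
                f"(length {self.length})"
            )
        if self.cen_start <= position <= self.cen_end:
            return None
        if position < self.cen_start:
            return f"{self.chromosome}p"
        return f"{self.chromosome}q"


class ArmModel:
    """Per-chromosome arm geometry for one genome build.

    Provides arm-label validation for GISTIC-style broad tables, the
    centromere/telomere filter for focal regions, and the coordinate
    frame for the segment simulator.
    """

    def __init__(self, chromosomes: dict[str, ChromosomeArms]):
        self.chromosomes = dict(chromosomes)

    @classmethod
    def from_tsv(cls, path) -> "ArmModel":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        required = {"chromosome", "length", "cen_start", "cen_end", "acrocentric"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"arm model file missing columns: {sorted(missing)}")
        chroms = {}
        for row in df.itertuples(index=False):
            chroms[row.chromosome] = ChromosomeArms(
                chromosome=row.chromosome,
                length=int(row.length),
                cen_start=int(row.cen_start),
                cen_end=int(row.cen_end),
                acrocentric=bool(row.acrocentric),
            )
        return cls(chroms)

    @classmethod
    def _packaged(cls, name: str) -> "ArmModel":
        ref = resources.files("oncoage.data").joinpath(name)
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @classmethod
    def hg19(cls) -> "ArmModel":
        """hg19 chromosome lengths and centromere intervals (UCSC gap track)."""
        return cls._packaged("hg19_arms.tsv")

    @classmethod
    def toy(cls) -> "ArmModel":
        """Three-chromosome miniature genome used in tests and fast simulation."""
        return cls._packaged("toy_arms.tsv")

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.chromosomes

    def __getitem__(self, chromosome: str) -> ChromosomeArms:
        return self.chromosomes[chromosome]

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in ("X", "Y")]

    @property
    def arm_labels(self) -> list[str]:
        out: list[str] = []
        for c in self.chromosomes.values():
            out.extend(c.arm_labels)
        return out

    def validate_arm(self, label: str) -> tuple[str, str]:
        """Split an arm label like '17p' into (chromosome, arm); raise if invalid."""
        if not label or label[-1] not in "pq":
            raise ValueError(f"malformed arm label {label!r}")
        chrom, arm = label[:-1], label[-1]
        if chrom not in self.chromosomes:
            raise ValueError(f"arm label {label!r}: unknown chromosome {chrom!r}")
        if label not in self.chromosomes[chrom].arm_labels:
            raise ValueError(
                f"arm label {label!r}: chromosome {chrom} has no {arm} arm"
            )
        return chrom, arm

    def autosomal_length(self) -> int:
        return sum(self.chromosomes[c].length for c in self.autosomes)
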
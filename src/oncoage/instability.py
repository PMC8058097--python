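"""Per-tumour genome-instability metrics from allele-specific segments.

The GI score is the percent of measured autosomal genome whose
(major, minor) allele state departs from the ground state — 1+1 for
tumours without whole-genome duplication (WGD), 2+2 after WGD.  LOH
segments retain exactly one parental allele (minor = 0, major >= 1);
homozygous deletions (0+0) are not LOH.  Sex chromosomes are excluded
from all denominators, and denominators use measured segment length,
so unprofiled gaps never count.

When a WGD flag is not supplied upstream, it is called from ploidy and
the LOH genome fraction with the linear boundary
``ploidy > tau0 - tau1 * loh_fraction`` (defaults tau0=2.9, tau1=2.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import SegmentProfile

WGD_TAU0_DEFAULT = 2.9
WGD_TAU1_DEFAULT = 2.0


class EmptyProfileError(ValueError):
    """No autosomal segments: ploidy/GI/LOH undefined."""


@dataclass(frozen=True)
class InstabilitySummary:
    """Per-tumour instability metrics (percent scales in [0, 100])."""

    sample_id: str
    ploidy: float
    gi_score: float
    percent_loh: float
    wgd: bool

    @property
    def loh_fraction(self) -> float:
        return self.percent_loh / 100.0


def _autosomal(profile: SegmentProfile) -> pd.DataFrame:
    seg = profile.autosomal
    if seg.empty:
        raise EmptyProfileError(
            f"sample {profile.sample_id}: no autosomal segments"
        )
    return seg


def tumour_ploidy(profile: SegmentProfile) -> float:
    """Length-weighted mean total copy number over autosomes."""
    seg = _autosomal(profile)
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    total = (seg["n_major"] + seg["n_minor"]).to_numpy(dtype=float)
    return float((lengths * total).sum() / lengths.sum())


def gi_score(profile: SegmentProfile, wgd: bool) -> float:
    """Percent of measured autosomal length off the ground state.

    Ground state is 1+1 for non-WGD tumours, 2+2 for WGD tumours.
    """
    seg = _autosomal(profile)
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    major, minor = (2, 2) if wgd else (1, 1)
    off = (seg["n_major"] != major) | (seg["n_minor"] != minor)
    return float(100.0 * lengths[off.to_numpy()].sum() / lengths.sum())


def percent_loh(profile: SegmentProfile) -> float:
    """Percent of measured autosomal length with exactly one parental allele."""
    seg = _autosomal(profile)
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    loh = (seg["n_minor"] == 0) & (seg["n_major"] >= 1)
    return float(100.0 * lengths[loh.to_numpy()].sum() / lengths.sum())


def call_wgd(
    ploidy: float,
    loh_fraction: float,
    tau0: float = WGD_TAU0_DEFAULT,
    tau1: float = WGD_TAU1_DEFAULT,
) -> bool:
    """Whole-genome duplication call from ploidy and LOH genome fraction."""
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    if not 0.0 <= loh_fraction <= 1.0:
        raise ValueError(f"loh_fraction must be in [0, 1], got {loh_fraction}")
    return bool(ploidy > tau0 - tau1 * loh_fraction)


def summarize(
    profile: SegmentProfile,
    tau0: float = WGD_TAU0_DEFAULT,
    tau1: float = WGD_TAU1_DEFAULT,
) -> InstabilitySummary:
    """All instability metrics for one tumour.

    Uses the profile's supplied ploidy/WGD when present, otherwise
    derives ploidy as the length-weighted mean copy number and calls
    WGD from the (ploidy, LOH fraction) boundary.
    """
    seg = _autosomal(profile)
    lengths = (seg["end"].to_numpy() - seg["start"].to_numpy() + 1).astype(float)
    nmaj = seg["n_major"].to_numpy()
    nmin = seg["n_minor"].to_numpy()
    total = lengths.sum()
    if profile.ploidy is not None:
        ploidy = profile.ploidy
    else:
        ploidy = float((lengths * (nmaj + nmin)).sum() / total)
    loh_pct = float(100.0 * lengths[(nmin == 0) & (nmaj >= 1)].sum() / total)
    wgd = profile.wgd
    if wgd is None:
        wgd = call_wgd(ploidy, loh_pct / 100.0, tau0=tau0, tau1=tau1)
    gmaj, gmin = (2, 2) if wgd else (1, 1)
    gi = float(100.0 * lengths[(nmaj != gmaj) | (nmin != gmin)].sum() / total)
    return InstabilitySummary(
        sample_id=profile.sample_id,
        ploidy=float(ploidy),
        gi_score=gi,
        percent_loh=loh_pct,
        wgd=bool(wgd),
    )


def cohort_summary(
    profiles: list[SegmentProfile],
    tau0: float = WGD_TAU0_DEFAULT,
    tau1: float = WGD_TAU1_DEFAULT,
) -> pd.DataFrame:
    """Instability metrics for a cohort, one row per sample."""
    rows = [summarize(p, tau0=tau0, tau1=tau1) for p in profiles]
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in rows],
            "ploidy": [r.ploidy for r in rows],
            "gi_score": [r.gi_score for r in rows],
            "percent_loh": [r.percent_loh for r in rows],
            "wgd": [r.wgd for r in rows],
        }
    )
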
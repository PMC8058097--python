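"""End-to-end orchestration of the three analysis tracks.

Runs instability -> SCNA -> mutations -> age associations -> the
expression/methylation track, as toggled in the config, writing every
output as TSV with a provenance metadata header (version, config hash,
seed) and logging per-stage sample counts and exclusions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as oio
from .association import AgeAssociationCascade
from .exprmeth import (
    age_feature_regression,
    classify_overlap,
    correlation_groups,
    filter_expressed,
    log2_expr,
    make_ranked_list,
    map_probes,
)
from .genome import ArmModel
from .instability import cohort_summary
from .mutations import (
    age_group_split,
    filter_nonsilent,
    gene_mutation_matrix,
    hypermutation_enrichment,
    mutation_burden,
)
from .scna import filter_focal_regions, scna_scores

log = logging.getLogger("oncoage")


@dataclass
class PipelineConfig:
    """Input paths, toggles and global thresholds for one run."""

    outdir: str
    clinical: str
    segments: str | None = None
    maf: str | None = None
    mutation_flags: str | None = None
    broad: str | None = None
    focal: str | None = None
    expression: str | None = None
    methylation: str | None = None
    probe_map: str | None = None
    arm_model: str | None = None  # None -> packaged hg19; 'toy' -> toy genome
    cohort_col: str = "cancer_type"
    seed: int = 0
    adj_p_cutoff: float = 0.05
    hypermutation_threshold: int = 1000
    gene_min_frequency: float = 0.05
    expression_min_fraction: float = 0.5
    max_missing: float = 0.10
    wgd_tau0: float = 2.9
    wgd_tau1: float = 2.0
    run_instability: bool = True
    run_scna: bool = True
    run_mutations: bool = True
    run_expr_meth: bool = True
    covariate_candidates: tuple = (
        "gender", "race", "stage", "grade", "smoking", "alcohol",
    )

    def __post_init__(self):
        if not 0 < self.adj_p_cutoff < 1:
            raise ValueError("adj_p_cutoff must lie in (0, 1)")
        for name in ("hypermutation_threshold", "gene_min_frequency",
                     "expression_min_fraction", "max_missing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, family: str = ""):
    with open(path, "w") as fh:
        fh.write(f"# oncoage {__version__} config={config.config_hash()} "
                 f"seed={config.seed} bh_family={family}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the results directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(config.clinical).exists():
        raise FileNotFoundError(f"clinical table not found: {config.clinical}")
    for name in ("segments", "maf", "broad", "focal", "expression",
                 "methylation", "probe_map", "mutation_flags"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name} input not found: {p}")

    if config.arm_model == "toy":
        arm_model = ArmModel.toy()
    elif config.arm_model:
        arm_model = ArmModel.from_tsv(config.arm_model)
    else:
        arm_model = ArmModel.hg19()

    clinical = oio.read_clinical(config.clinical)
    log.info("clinical: %d samples", len(clinical))
    candidates = list(config.covariate_candidates)

    def cascade(outcome: pd.Series, kind: str) -> pd.DataFrame:
        model = AgeAssociationCascade.from_dataframe(
            outcome,
            clinical,
            kind=kind,
            cohort_col=config.cohort_col,
            covariate_candidates=candidates,
            alpha=config.adj_p_cutoff,
            max_missing=config.max_missing,
        )
        return model.fit().table

    stage = "instability"
    try:
        if config.run_instability and config.segments:
            profiles = oio.read_segments(config.segments, arm_model)
            summary = cohort_summary(
                profiles, tau0=config.wgd_tau0, tau1=config.wgd_tau1
            )
            _write_tsv(summary, out / "instability.tsv", config)
            for col, kind in (("gi_score", "continuous"),
                              ("percent_loh", "continuous"),
                              ("wgd", "binary")):
                vals = summary.set_index("sample")[col].astype(float)
                table = cascade(vals, kind)
                _write_tsv(table, out / f"assoc_{col}.tsv", config, f"{col}")

        stage = "scna"
        if config.run_scna and config.broad and config.focal:
            broad = oio.read_gistic_broad(config.broad, arm_model)
            focal = oio.read_focal_events(config.focal, arm_model)
            n_before = len(focal)
            focal = filter_focal_regions(
                focal.rename(columns={"sample": "sample"}), arm_model
            )
            log.info("scna: %d/%d focal events pass centromere/telomere filter",
                     len(focal), n_before)
            cohorts = clinical.set_index("sample_id")[config.cohort_col]
            scores = scna_scores(broad, focal, cohorts, arm_model)
            _write_tsv(scores, out / "scna_scores.tsv", config)
            for col in ("overall", "chrom_arm", "focal_norm"):
                vals = scores.set_index("sample")[col].astype(float)
                table = cascade(vals, "continuous")
                _write_tsv(table, out / f"assoc_scna_{col}.tsv", config, f"scna_{col}")

        stage = "mutations"
        if config.run_mutations and config.maf:
            maf = oio.read_maf_minimal(config.maf)
            nonsilent = filter_nonsilent(maf)
            burden = mutation_burden(nonsilent, samples=clinical["sample_id"])
            _write_tsv(burden, out / "mutation_burden.tsv", config)
            ages = clinical.set_index("sample_id")["age"]
            groups = age_group_split(ages)
            enrich = hypermutation_enrichment(
                burden.set_index("sample")["hypermutated"], groups
            )
            pd.DataFrame([{
                "young_pct": enrich["young_pct"],
                "old_pct": enrich["old_pct"],
                "fisher_p": enrich["fisher_p"],
            }]).pipe(_write_tsv, out / "hypermutation_enrichment.tsv", config)
            vals = burden.set_index("sample")["log_burden"].astype(float)
            _write_tsv(cascade(vals, "continuous"), out / "assoc_burden.tsv",
                       config, "burden")
            # gene-level screen on the restricted cohort
            keep = burden.set_index("sample")["burden"] < config.hypermutation_threshold
            if config.mutation_flags:
                flags = pd.read_csv(config.mutation_flags, sep="\t").set_index("sample_id")
                if "msi_high" in flags:
                    keep &= ~flags["msi_high"].reindex(keep.index, fill_value=False)
            cohort_samples = [s for s in clinical["sample_id"] if keep.get(s, False)]
            log.info("mutations: %d/%d samples retained for gene-level analysis",
                     len(cohort_samples), len(clinical))
            gene_mat = gene_mutation_matrix(
                nonsilent, cohort_samples, config.gene_min_frequency
            )
            _write_tsv(gene_mat.reset_index(), out / "gene_matrix.tsv", config)

        stage = "expr_meth"
        if config.run_expr_meth and config.expression and config.methylation:
            expr = oio.read_matrix(config.expression, "expression")
            meth = oio.read_matrix(config.methylation, "methylation")
            probe_map = oio.read_probe_map(config.probe_map)
            expr = filter_expressed(expr, config.expression_min_fraction)
            lexpr = log2_expr(expr)
            gene_meth, mapping = map_probes(meth, probe_map, lexpr)
            from .association import covariate_select

            covs = covariate_select(clinical, candidates, config.max_missing)
            expr_res = age_feature_regression(lexpr, clinical, covs,
                                              alpha=config.adj_p_cutoff)
            meth_res = age_feature_regression(gene_meth, clinical, covs,
                                              alpha=config.adj_p_cutoff)
            _write_tsv(expr_res.reset_index(), out / "age_degs.tsv", config, "expr")
            _write_tsv(meth_res.reset_index(), out / "age_dmgs.tsv", config, "meth")
            overlap = classify_overlap(expr_res, meth_res)
            pd.DataFrame([{
                **overlap.quadrant_counts,
                "n_overlap": overlap.n_overlap,
                "opposite_pct": overlap.opposite_pct,
            }]).pipe(_write_tsv, out / "overlap_quadrants.tsv", config)
            table, tests = correlation_groups(lexpr, gene_meth, expr_res, meth_res)
            _write_tsv(table.reset_index(), out / "correlation_groups.tsv", config)
            _write_tsv(tests.dunn, out / "correlation_dunn.tsv", config)
            _write_tsv(make_ranked_list(expr_res), out / "ranked_expr.tsv", config)
            _write_tsv(make_ranked_list(meth_res), out / "ranked_meth.tsv", config)
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        raise PipelineError(stage, err) from err
    return out
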
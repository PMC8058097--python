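"""Synthetic tumour cohorts with planted age effects.

The generator emulates the statistical structure the analysis assumes:
age-dependent genomic instability and LOH, logit-linear WGD odds,
clock-like (log-linear) mutation accumulation with an age-increasing
C>T share, a young-enriched hypermutator subpopulation, age-dependent
arm gain odds, and expression/methylation matrices in which planted age
genes gain methylation with age and lose expression through a negative
methylation->expression coupling.  Planted truth is returned alongside
every table so recovery tests can compare estimates with ground truth.

All randomness flows through a single ``numpy.random.Generator``
(PCG64), so identical parameters and seed give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .containers import MutationTable, OmicsMatrix, SegmentProfile
from .genome import ArmModel


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulationParams:
    """Cohort generator settings.

    Defaults describe the "endometrial-like" scenario: rising genome
    instability, WGD and mutation burden with age, an age-increasing
    C>T fraction, hypermutators enriched in patients aged <= 50, and
    negative methylation->expression coupling at the planted age genes.
    """

    n_samples: int = 400
    seed: int = 0
    cancer_type: str = "SIM"
    age_min: int = 30
    age_max: int = 85

    # segment layer: fractions of measured genome per year of age
    gi_base: float = 0.05          # non-ground fraction at age 0 reference
    gi_slope: float = 0.003        # fraction / year (0.3 %/yr)
    gi_noise: float = 0.05
    loh_ratio_base: float = 0.25   # LOH share of the non-ground fraction
    loh_ratio_slope: float = 0.002
    loh_ratio_noise: float = 0.05
    wgd_logit_intercept: float = -2.34
    wgd_logit_slope: float = 0.03  # per year

    # mutation layer
    burden_log_intercept: float = 4.5   # natural-log Poisson mean
    burden_log_slope: float = 0.01      # per year
    ct_base: float = 0.10               # C>T share at age 0 reference
    ct_fraction_slope: float = 0.004    # per year
    hypermutator_rate_young: float = 0.34
    hypermutator_rate_old: float = 0.11
    hypermutator_extra_mean: float = 800.0
    n_background_genes: int = 200
    n_driver_genes: int = 10
    driver_base_logit: float = -2.0
    driver_or_per_year: float = 1.0
    silent_fraction: float = 0.10

    # expression / methylation layer
    n_genes: int = 1000
    n_age_genes: int = 50
    meth_age_slope: float = 0.003   # beta per year
    meth_noise: float = 0.03
    coupling: float = -4.0          # log2-expression change per beta unit
    expr_noise: float = 0.5
    max_probes_per_gene: int = 3

    # GISTIC-like layer
    arm_gain_or_per_year: float = 1.03
    arm_gain_base_logit: float = -1.7
    n_age_arms: int = 2
    background_event_rate: float = 0.20
    chrom_event_rate: float = 0.25
    n_focal_regions: int = 6
    focal_event_rate: float = 0.15

    def __post_init__(self):
        for name in (
            "hypermutator_rate_young",
            "hypermutator_rate_old",
            "background_event_rate",
            "chrom_event_rate",
            "focal_event_rate",
            "silent_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_age_genes > self.n_genes:
            raise ValueError("n_age_genes exceeds n_genes")
        for name in ("gi_noise", "meth_noise", "expr_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        mean_f = self.gi_base + self.gi_slope * self.age_max
        if not 0.0 < mean_f <= 1.0:
            raise ValueError(
                "gi_base/gi_slope put the mean non-ground fraction outside (0, 1] "
                f"at age {self.age_max}"
            )


def load_scenario(name: str, **overrides) -> SimulationParams:
    """Load a packaged scenario preset ('null', 'endometrial-like', 'glioma-like')."""
    fname = name.replace("-", "_") + ".yaml"
    ref = resources.files("oncoage.data").joinpath("scenarios").joinpath(fname)
    with ref.open() as fh:
        values = yaml.safe_load(fh) or {}
    values.update(overrides)
    valid = {f.name for f in fields(SimulationParams)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"scenario {name!r}: unknown keys {sorted(unknown)}")
    return SimulationParams(**values)


# ---------------------------------------------------------------------------
# clinical


def simulate_clinical(params: SimulationParams, rng=None) -> pd.DataFrame:
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = params.n_samples
    ids = [f"S{i:05d}" for i in range(n)]
    ages = rng.integers(params.age_min, params.age_max + 1, size=n)
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "age": ages,
            "cancer_type": params.cancer_type,
            "gender": rng.choice(["female", "male"], size=n, p=[0.6, 0.4]),
            "race": rng.choice(
                ["white", "black", "asian", "other"], size=n, p=[0.7, 0.15, 0.1, 0.05]
            ),
            "stage": rng.choice(
                ["I", "II", "III", "IV", ""], size=n, p=[0.35, 0.3, 0.2, 0.1, 0.05]
            ),
            "grade": rng.choice(
                ["G1", "G2", "G3", ""], size=n, p=[0.3, 0.4, 0.25, 0.05]
            ),
            "smoking": rng.choice(
                ["never", "former", "current", ""], size=n, p=[0.5, 0.25, 0.17, 0.08]
            ),
            "alcohol": rng.choice(["no", "yes", ""], size=n, p=[0.55, 0.37, 0.08]),
            "purity": np.round(rng.beta(5, 2, size=n), 4),
        }
    )
    df = df.replace({"": np.nan})
    return df


# ---------------------------------------------------------------------------
# segments


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def plant_profile(
    sample_id: str,
    nonground_fraction: float,
    loh_share: float,
    wgd: bool,
    arm_model: ArmModel,
    rng,
    purity: float | None = None,
) -> tuple[SegmentProfile, float, float]:
    """Build one profile with an exact planted non-ground length fraction.

    Returns (profile, realized non-ground fraction, realized LOH
    fraction); the realized fractions are the planted ones quantised to
    whole bases, so ``gi_score`` recovers them exactly.
    """
    autosomes = arm_model.autosomes
    lengths = np.array([arm_model[c].length for c in autosomes], dtype=np.int64)
    total = int(lengths.sum())
    ng_total = int(round(np.clip(nonground_fraction, 0.0, 1.0) * total))
    loh_total = int(round(np.clip(loh_share, 0.0, 1.0) * ng_total))
    ng_by_chrom = _largest_remainder(ng_total, lengths.astype(float))
    loh_by_chrom = _largest_remainder(loh_total, np.maximum(ng_by_chrom, 1).astype(float))
    loh_by_chrom = np.minimum(loh_by_chrom, ng_by_chrom)
    ground = (2, 2) if wgd else (1, 1)
    loh_state = (2, 0) if wgd else (1, 0)
    alt_states = [(3, 2), (4, 2)] if wgd else [(2, 1), (3, 1)]
    rows = []
    for chrom, length, m, l in zip(autosomes, lengths, ng_by_chrom, loh_by_chrom):
        pos = 1
        if l > 0:
            rows.append((chrom, pos, pos + l - 1, *loh_state))
            pos += l
        alt_len = m - l
        if alt_len > 0:
            nmaj, nmin = alt_states[rng.integers(0, len(alt_states))]
            rows.append((chrom, pos, pos + alt_len - 1, nmaj, nmin))
            pos += alt_len
        if pos <= length:
            # occasionally split the ground stretch; metrics are split-invariant
            if length - pos > 10 and rng.random() < 0.5:
                cut = int(rng.integers(pos, length))
                rows.append((chrom, pos, cut, *ground))
                rows.append((chrom, cut + 1, length, *ground))
            else:
                rows.append((chrom, pos, length, *ground))
    seg = pd.DataFrame(
        {
            "chromosome": np.array([r[0] for r in rows], dtype=object),
            "start": np.array([r[1] for r in rows], dtype=np.int64),
            "end": np.array([r[2] for r in rows], dtype=np.int64),
            "n_major": np.array([r[3] for r in rows], dtype=np.int64),
            "n_minor": np.array([r[4] for r in rows], dtype=np.int64),
        }
    )
    profile = SegmentProfile(
        sample_id=sample_id, segments=seg, purity=purity, wgd=wgd
    )
    return profile, ng_total / total, loh_total / total


def simulate_segments(
    clinical: pd.DataFrame,
    params: SimulationParams,
    arm_model: ArmModel,
    rng=None,
) -> tuple[list[SegmentProfile], pd.DataFrame]:
    """Per-sample segment profiles; returns (profiles, planted truth)."""
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    profiles, truth = [], []
    for row in clinical.itertuples(index=False):
        age = float(row.age)
        wgd_p = _logistic(params.wgd_logit_intercept + params.wgd_logit_slope * age)
        wgd = bool(rng.random() < wgd_p)
        f = float(
            np.clip(
                params.gi_base
                + params.gi_slope * age
                + rng.normal(0.0, params.gi_noise),
                0.0,
                1.0,
            )
        )
        share = float(
            np.clip(
                params.loh_ratio_base
                + params.loh_ratio_slope * age
                + rng.normal(0.0, params.loh_ratio_noise),
                0.0,
                1.0,
            )
        )
        profile, f_real, loh_real = plant_profile(
            row.sample_id, f, share, wgd, arm_model, rng,
            purity=getattr(row, "purity", None),
        )
        profiles.append(profile)
        truth.append((row.sample_id, age, wgd, f_real, loh_real))
    truth_df = pd.DataFrame(
        truth, columns=["sample_id", "age", "wgd", "nonground_fraction", "loh_fraction"]
    )
    return profiles, truth_df


# ---------------------------------------------------------------------------
# mutations

_SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CLASS_REF = np.array([c[0] for c in _SUB_CLASSES])
_CLASS_ALT = np.array([c[2] for c in _SUB_CLASSES])
_CLASS_REF_C = np.array([_COMPLEMENT[c[0]] for c in _SUB_CLASSES])
_CLASS_ALT_C = np.array([_COMPLEMENT[c[2]] for c in _SUB_CLASSES])


def simulate_mutations(
    clinical: pd.DataFrame,
    params: SimulationParams,
    gene_list: list[str] | None = None,
    rng=None,
) -> tuple[MutationTable, pd.DataFrame]:
    """Variant table plus per-sample flags (hypermutator truth, MSI-H, POLE).

    Non-hypermutated burden is Poisson with a log-linear age trend; the
    C>T share of SNVs rises linearly with age; driver-gene carriage is
    Bernoulli with a per-year odds ratio; hypermutators (burden forced
    above 1000) occur at age-group-specific rates and carry an MSI-H or
    POLE flag.  A ``silent_fraction`` of extra Silent rows exercises the
    non-silent filter.
    """
    rng = np.random.default_rng(params.seed + 2) if rng is None else rng
    if gene_list is None:
        gene_list = [f"DRV{i:03d}" for i in range(params.n_driver_genes)]
    if not gene_list:
        raise ValueError("empty driver gene list")
    background = [f"GENE{i:04d}" for i in range(params.n_background_genes)]
    log_or = np.log(params.driver_or_per_year)

    all_rows: dict[str, list] = {
        "Hugo_Symbol": [],
        "Tumor_Sample_Barcode": [],
        "Variant_Classification": [],
        "Reference_Allele": [],
        "Tumor_Seq_Allele2": [],
    }
    flags = []
    for row in clinical.itertuples(index=False):
        age = float(row.age)
        young = age <= 50
        hyper_rate = (
            params.hypermutator_rate_young if young else params.hypermutator_rate_old
        )
        hyper = bool(rng.random() < hyper_rate)
        lam = float(np.exp(params.burden_log_intercept + params.burden_log_slope * age))
        if hyper:
            burden = 1001 + int(rng.poisson(params.hypermutator_extra_mean))
        else:
            burden = int(rng.poisson(lam))
        msi = bool(hyper and rng.random() < 0.6)
        pole = bool(hyper and not msi)

        p_ct = float(np.clip(params.ct_base + params.ct_fraction_slope * age, 0.02, 0.9))
        p_rest = (1.0 - p_ct) / 5.0
        probs = [p_rest, p_rest, p_ct, p_rest, p_rest, p_rest]
        classes = rng.choice(len(_SUB_CLASSES), size=burden, p=probs)
        ref_arr = _CLASS_REF[classes].copy()
        alt_arr = _CLASS_ALT[classes].copy()
        flip = rng.random(burden) < 0.5  # purine-strand representation
        ref_arr[flip] = _CLASS_REF_C[classes[flip]]
        alt_arr[flip] = _CLASS_ALT_C[classes[flip]]
        refs = ref_arr.tolist()
        alts = alt_arr.tolist()
        genes = rng.choice(background, size=burden).tolist()
        vclass = ["Missense_Mutation"] * burden

        # driver-gene carriage with per-year odds
        for g in gene_list:
            p_g = _logistic(params.driver_base_logit + log_or * age)
            if rng.random() < p_g:
                genes.append(g)
                vclass.append("Missense_Mutation")
                refs.append("C")
                alts.append("T")
        if pole:
            genes.append("POLE")
            vclass.append("Missense_Mutation")
            refs.append("C")
            alts.append("A")
        n_silent = int(rng.poisson(params.silent_fraction * max(burden, 1)))
        if n_silent:
            genes.extend(rng.choice(background, size=n_silent).tolist())
            vclass.extend(["Silent"] * n_silent)
            refs.extend(["G"] * n_silent)
            alts.extend(["A"] * n_silent)

        n_rows = len(genes)
        all_rows["Hugo_Symbol"].extend(genes)
        all_rows["Tumor_Sample_Barcode"].extend([row.sample_id] * n_rows)
        all_rows["Variant_Classification"].extend(vclass)
        all_rows["Reference_Allele"].extend(refs)
        all_rows["Tumor_Seq_Allele2"].extend(alts)
        flags.append((row.sample_id, age, hyper, msi, pole, burden))

    table = MutationTable(records=pd.DataFrame(all_rows))
    flags_df = pd.DataFrame(
        flags,
        columns=["sample_id", "age", "hypermutator", "msi_high", "pole_mut", "burden_truth"],
    )
    flags_df["pold1_mut"] = False
    return table, flags_df


# ---------------------------------------------------------------------------
# expression / methylation


def simulate_expr_meth(
    clinical: pd.DataFrame,
    params: SimulationParams,
    rng=None,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame, pd.DataFrame]:
    """Expression (RSEM), probe-level methylation, probe map and truth.

    Age genes follow beta = clip01(mu + slope*age + eps) and
    log2 expression = nu + coupling*beta + delta; other genes are pure
    noise.  Each gene carries one signal probe and up to two noise-only
    decoys.
    """
    rng = np.random.default_rng(params.seed + 3) if rng is None else rng
    n = len(clinical)
    ages = clinical["age"].to_numpy(dtype=float)
    samples = clinical["sample_id"].tolist()
    n_age = params.n_age_genes
    genes = [f"AG{i:04d}" for i in range(n_age)] + [
        f"BG{i:04d}" for i in range(params.n_genes - n_age)
    ]
    mu = rng.uniform(0.15, 0.5, size=params.n_genes)
    nu = rng.uniform(4.0, 8.0, size=params.n_genes)

    beta = np.empty((params.n_genes, n))
    logx = np.empty((params.n_genes, n))
    for g in range(params.n_genes):
        eps = rng.normal(0.0, params.meth_noise, size=n)
        if g < n_age:
            beta[g] = np.clip(mu[g] + params.meth_age_slope * ages + eps, 0.0, 1.0)
            logx[g] = (
                nu[g]
                + params.coupling * beta[g]
                + rng.normal(0.0, params.expr_noise, size=n)
            )
        else:
            beta[g] = np.clip(mu[g] + eps, 0.0, 1.0)
            logx[g] = nu[g] + rng.normal(0.0, params.expr_noise, size=n)
    rsem = np.maximum(np.exp2(logx) - 1.0, 0.0)
    expr = OmicsMatrix(
        values=pd.DataFrame(rsem, index=genes, columns=samples), kind="expression"
    )

    probe_rows, meth_rows, meth_index, truth = [], [], [], []
    for g, gene in enumerate(genes):
        n_probes = int(rng.integers(1, params.max_probes_per_gene + 1))
        signal_slot = int(rng.integers(0, n_probes))
        for k in range(n_probes):
            probe = f"{gene}_p{k}"
            if k == signal_slot:
                vals = beta[g]
            else:
                vals = np.clip(
                    rng.uniform(0.15, 0.5)
                    + rng.normal(0.0, params.meth_noise, size=n),
                    0.0,
                    1.0,
                )
            meth_rows.append(vals)
            meth_index.append(probe)
            probe_rows.append((probe, gene))
        truth.append((gene, g < n_age, f"{gene}_p{signal_slot}", mu[g], nu[g]))
    meth = OmicsMatrix(
        values=pd.DataFrame(
            np.vstack(meth_rows), index=meth_index, columns=samples
        ),
        kind="methylation",
    )
    probe_map = pd.DataFrame(probe_rows, columns=["probe", "gene"])
    truth_df = pd.DataFrame(
        truth, columns=["gene", "is_age_gene", "signal_probe", "mu", "nu"]
    )
    return expr, meth, probe_map, truth_df


# ---------------------------------------------------------------------------
# GISTIC-like events


def simulate_gistic_events(
    clinical: pd.DataFrame,
    params: SimulationParams,
    arm_model: ArmModel,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Broad (arm x sample) and focal event tables with planted age arms.

    The first ``n_age_arms`` arm labels carry gains with logit-linear
    age odds; remaining arms gain or lose at a constant background rate,
    and whole chromosomes alter both arms identically at
    ``chrom_event_rate``.  Focal lesions sit mid-arm, clear of
    centromere/telomere windows.
    """
    rng = np.random.default_rng(params.seed + 4) if rng is None else rng
    arms = arm_model.arm_labels
    age_arms = arms[: params.n_age_arms]
    samples = clinical["sample_id"].tolist()
    ages = clinical["age"].to_numpy(dtype=float)
    log_or = np.log(params.arm_gain_or_per_year)

    broad = pd.DataFrame(0.0, index=arms, columns=samples)
    for j, sample in enumerate(samples):
        age = ages[j]
        for chrom in arm_model.chromosomes:
            labels = arm_model[chrom].arm_labels
            if rng.random() < params.chrom_event_rate:
                v = rng.normal(0.5, 0.1) * (1 if rng.random() < 0.5 else -1)
                for lab in labels:
                    broad.loc[lab, sample] = v
                continue
            for lab in labels:
                if lab in age_arms:
                    p_gain = _logistic(params.arm_gain_base_logit + log_or * age)
                    if rng.random() < p_gain:
                        broad.loc[lab, sample] = rng.normal(0.5, 0.1)
                elif rng.random() < params.background_event_rate:
                    sign = 1 if rng.random() < 0.5 else -1
                    broad.loc[lab, sample] = sign * rng.normal(0.5, 0.1)

    # focal region pool mid-arm, away from centromeres/telomeres
    regions = []
    i = 0
    for chrom in arm_model.chromosomes:
        if chrom in ("X", "Y"):
            continue
        cm = arm_model[chrom]
        for extent in (cm.p_extent, cm.q_extent):
            if extent is None:
                continue
            lo, hi = extent
            mid = (lo + hi) // 2
            width = max((hi - lo) // 20, 2)
            regions.append((f"FR{i:02d}", chrom, mid - width // 2, mid + width // 2))
            i += 1
            if len(regions) >= params.n_focal_regions:
                break
        if len(regions) >= params.n_focal_regions:
            break

    focal_rows = []
    for sample in samples:
        for name, chrom, start, end in regions:
            if rng.random() < params.focal_event_rate:
                sign = 1 if rng.random() < 0.5 else -1
                focal_rows.append(
                    (sample, name, chrom, start, end, sign * rng.normal(0.9, 0.2))
                )
    focal = pd.DataFrame(
        focal_rows,
        columns=["sample", "region", "chromosome", "start", "end", "log2_ratio"],
    )
    truth = {"age_arms": list(age_arms), "regions": regions}
    return broad, focal, truth


# ---------------------------------------------------------------------------
# whole cohort


@dataclass
class SimulatedCohort:
    """All tables of one synthetic cohort, with planted truth attached."""

    params: SimulationParams
    clinical: pd.DataFrame
    profiles: list[SegmentProfile]
    segment_truth: pd.DataFrame
    mutations: MutationTable
    mutation_flags: pd.DataFrame
    expression: OmicsMatrix
    methylation: OmicsMatrix
    probe_map: pd.DataFrame
    expr_meth_truth: pd.DataFrame
    broad: pd.DataFrame
    focal: pd.DataFrame
    gistic_truth: dict = field(default_factory=dict)


def simulate_cohort(
    params: SimulationParams, arm_model: ArmModel | None = None
) -> SimulatedCohort:
    """Generate every pipeline input for one cohort from one seed."""
    arm_model = ArmModel.toy() if arm_model is None else arm_model
    clinical = simulate_clinical(params)
    profiles, seg_truth = simulate_segments(clinical, params, arm_model)
    mutations, flags = simulate_mutations(clinical, params)
    expr, meth, probe_map, em_truth = simulate_expr_meth(clinical, params)
    broad, focal, gistic_truth = simulate_gistic_events(clinical, params, arm_model)
    return SimulatedCohort(
        params=params,
        clinical=clinical,
        profiles=profiles,
        segment_truth=seg_truth,
        mutations=mutations,
        mutation_flags=flags,
        expression=expr,
        methylation=meth,
        probe_map=probe_map,
        expr_meth_truth=em_truth,
        broad=broad,
        focal=focal,
        gistic_truth=gistic_truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write all cohort tables in the pipeline's TSV dialects."""
    from pathlib import Path

    from . import io as oio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    oio.write_clinical(cohort.clinical, out / "clinical.tsv")
    oio.write_segments(cohort.profiles, out / "segments.tsv")
    oio.write_maf(cohort.mutations, out / "mutations.maf")
    cohort.mutation_flags.to_csv(out / "mutation_flags.tsv", sep="\t", index=False)
    oio.write_matrix(cohort.expression, out / "expression.tsv")
    oio.write_matrix(cohort.methylation, out / "methylation.tsv")
    cohort.probe_map.to_csv(out / "probe_map.tsv", sep="\t", index=False)
    oio.write_gistic_broad(cohort.broad, out / "broad.tsv")
    oio.write_focal_events(cohort.focal, out / "focal.tsv")


def null_params(**overrides) -> SimulationParams:
    """All planted age effects switched off."""
    base = dict(
        gi_slope=0.0,
        loh_ratio_slope=0.0,
        wgd_logit_slope=0.0,
        burden_log_slope=0.0,
        ct_fraction_slope=0.0,
        hypermutator_rate_young=0.0,
        hypermutator_rate_old=0.0,
        driver_or_per_year=1.0,
        meth_age_slope=0.0,
        coupling=0.0,
        arm_gain_or_per_year=1.0,
    )
    base.update(overrides)
    return SimulationParams(**base)
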
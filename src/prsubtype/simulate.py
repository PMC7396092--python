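"""Synthetic cohorts with controlled pleiotropy, latent subtypes and
clinical outcomes.

The generator emulates the data layout of a PRS-subtyping study: two
case/control discovery cohorts and one all-case trial cohort, genotyped at
M biallelic variants; GWAS summary statistics for a focal disease and K
candidate traits, of which a subset genuinely shares causal variants with
the focal disease; latent case subtypes defined by which shared genetic
component dominates; and pre/post clinical outcomes (symptom counts,
cognitive domains, laboratory panels) with class-specific treatment
effects.  Every quantity of interest is recorded in a TruthBundle so
recovery can be measured exactly.

Genetic model
-------------
Allele frequencies are Uniform(maf_range); each trait has an additive
effect vector nonzero on its causal block, with comorbid-trait blocks
lying inside the focal-disease block (shared variants carry effects for
both).  Liability is additive (genotype x effects + Gaussian noise) and
case status corresponds to liability above the prevalence threshold.
Case genotypes are drawn from the exponentially tilted genotype law --
the asymptotic conditional distribution of genotypes given liability
above the threshold: each causal variant's allele frequency is shifted on
the logit scale in proportion to its effect.  The focal tilt magnitude is
the inverse Mills ratio of the prevalence; each case additionally carries
a subtype-specific tilt on the blocks of its subtype's traits, whose
magnitude (``subtype_separation``, in SD units of the trait burden) sets
how separable the planted subtypes are in PRS space.  The recorded
subtype label is the argmax over subtypes of the case's realized shared
genetic contribution.

Summary statistics are noisy estimates of the true effects from an
independent reference GWAS, simulated at the sufficient-statistic level:
beta_hat ~ N(beta, se^2) with the standard per-variant score-test SE, so
null variants have Uniform(0,1) p-values and block variants reach
genome-wide thresholds at rates controlled by the reference sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .io import GenotypeDataset, SummaryStatsTable
from .prs import PRSMatrix

FOCAL_TRAIT = "scz"

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    n_cases: int
    n_controls: int
    role: str = "discovery"  # "discovery" | "trial"


@dataclass(frozen=True)
class OutcomeSpec:
    """One clinical outcome: baseline law, change law and per-class effects.

    ``class_effects`` are the expected reported differences per latent
    subtype, already on the reporting sign convention of the family
    (symptoms: pre - post, positive = reduction; cognitive/lab:
    post - pre).
    """

    outcome_id: str
    family: str  # "symptom" | "cognitive" | "lab"
    visit_post: str  # "end_phase1" | "visit6"
    direction: str  # "pre_minus_post" | "post_minus_pre"
    baseline_mean: float
    baseline_sd: float
    change_sd: float
    class_effects: tuple[float, ...]
    family_size: int
    followup_rate: float = 1.0
    baseline_class_shift: tuple[float, ...] | None = None


def default_outcomes(n_subtypes: int = 4) -> list[OutcomeSpec]:
    """Outcome catalog emulating antipsychotic-trial measures.

    Four latent subtypes: a treatment-responsive class (symptom reduction
    plus broad cognitive improvement), a partial responder (total/positive
    symptoms and processing speed, with lower baseline symptoms), a
    treatment-resistant class with metabolic-panel shifts (phosphorus,
    HDL, calcium up), and a negative-symptom responder with an
    inflammation signature (lymphocytes down, neutrophils up).  Change
    noise SDs are on the scale of published trial tables (symptom-count
    change SD ~ 18 for total symptoms; cognitive z-score change SD ~ 0.55).
    """
    if n_subtypes != 4:
        raise SimulationError("default outcome catalog is defined for 4 subtypes")
    S = OutcomeSpec
    return [
        S("total_symptom", "symptom", "end_phase1", "pre_minus_post",
          55.0, 12.0, 18.0, (5.47, 3.90, 0.0, 1.50), 3,
          baseline_class_shift=(0.0, -4.0, 0.0, 0.0)),
        S("positive_symptom", "symptom", "end_phase1", "pre_minus_post",
          15.0, 5.0, 6.4, (1.26, 1.02, 0.0, 0.0), 3),
        S("negative_symptom", "symptom", "end_phase1", "pre_minus_post",
          16.0, 5.0, 5.9, (1.36, 0.65, 0.0, 2.18), 3,
          baseline_class_shift=(0.0, -2.0, 0.0, 0.0)),
        S("vigilance", "cognitive", "visit6", "post_minus_pre",
          0.0, 1.0, 0.55, (-0.23, 0.0, -0.41, -0.34), 4, followup_rate=0.52),
        S("processing_speed", "cognitive", "visit6", "post_minus_pre",
          0.0, 1.0, 0.55, (-0.20, -0.29, 0.0, -0.26), 4, followup_rate=0.52),
        S("working_memory", "cognitive", "visit6", "post_minus_pre",
          0.0, 1.0, 0.55, (-0.21, 0.0, 0.0, -0.26), 4, followup_rate=0.52),
        S("reasoning", "cognitive", "visit6", "post_minus_pre",
          0.0, 1.0, 0.55, (-0.28, 0.0, 0.0, -0.40), 4, followup_rate=0.52),
        S("hdl", "lab", "end_phase1", "post_minus_pre",
          45.0, 12.0, 9.6, (-2.25, 0.0, 2.22, 0.0), 5, followup_rate=0.96),
        S("calcium", "lab", "end_phase1", "post_minus_pre",
          9.5, 0.5, 0.5, (0.05, 0.05, 0.14, 0.05), 5, followup_rate=0.96),
        S("phosphorus", "lab", "end_phase1", "post_minus_pre",
          3.5, 0.6, 0.6, (0.0, 0.0, 0.19, 0.0), 5, followup_rate=0.96),
        S("lymphocytes", "lab", "end_phase1", "post_minus_pre",
          30.0, 8.0, 7.3, (0.0, 0.0, 0.0, -3.12), 5, followup_rate=0.96),
        S("neutrophils", "lab", "end_phase1", "post_minus_pre",
          60.0, 9.0, 8.5, (0.0, 0.0, 0.0, 3.04), 5, followup_rate=0.96),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults mirror the emulated study: discovery cohorts of 2,681 and
    2,895 cases (with comparable control counts) and a 435-case trial
    cohort; 25 candidate traits of which 10 genuinely share causal
    variants with the focal disease; 4 latent subtypes.
    """

    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.95)
    cohorts: tuple[CohortSpec, ...] = (
        CohortSpec("discovery_a", 2681, 2653, "discovery"),
        CohortSpec("discovery_b", 2895, 2895, "discovery"),
        CohortSpec("trial", 435, 0, "trial"),
    )
    n_traits: int = 25
    n_comorbid: int = 10
    n_shared: int = 40  # variants per (focal, trait) shared block
    n_focal_extra: int = 200  # focal-only causal variants
    effect_sd: float = 0.12  # per-variant causal effect SD
    prevalence: float = 0.01  # liability-threshold prevalence (sets focal tilt)
    reference_n: int = 20000  # reference GWAS size per trait
    n_subtypes: int = 4
    # Tilt magnitude per owned trait-burden coordinate, in SD units of the
    # true burden.  PRS estimation (noisy weights on a jointly selected
    # marker subset) attenuates this by roughly 15%, so 6.0 realizes a
    # minimum pairwise centroid separation of ~5-6x the within-subtype SD
    # in observed score space -- the separability regime the clustering
    # stage is designed to recover.
    subtype_separation: float = 6.0
    palindromic_rate: float = 0.02  # strand-ambiguous variants (dropped downstream)
    swap_rate: float = 0.05  # summary-stat rows reported on the opposite allele
    outcomes: tuple[OutcomeSpec, ...] = field(
        default_factory=lambda: tuple(default_outcomes())
    )

    def __post_init__(self):
        needed = self.n_traits * self.n_shared + self.n_focal_extra
        if self.n_variants < needed:
            raise SimulationError(
                f"n_variants={self.n_variants} < {needed} causal-block variants"
            )
        if not 0 < self.prevalence < 1:
            raise SimulationError("prevalence must be in (0, 1)")
        if self.n_comorbid > self.n_traits:
            raise SimulationError("n_comorbid cannot exceed n_traits")

    @property
    def trait_ids(self) -> list[str]:
        return [f"trait{i + 1:02d}" for i in range(self.n_traits)]

    @property
    def comorbid_traits(self) -> list[str]:
        return self.trait_ids[: self.n_comorbid]

    def trait_type(self, trait_id: str) -> str:
        if trait_id == FOCAL_TRAIT:
            return "binary"
        i = self.trait_ids.index(trait_id)
        return "binary" if i % 2 == 0 else "quantitative"

    def trait_direction(self, trait_id: str) -> int:
        """Sign of the trait's genetic correlation with the focal disease.

        Seven of the ten comorbid traits are positively correlated, three
        negatively (emulating e.g. wellbeing-like traits).
        """
        i = self.trait_ids.index(trait_id)
        return -1 if i in (4, 7, 9) else 1

    def subtype_of_trait(self, trait_id: str) -> int | None:
        """Comorbid traits are owned round-robin by the latent subtypes."""
        if trait_id not in self.comorbid_traits:
            return None
        return self.comorbid_traits.index(trait_id) % self.n_subtypes


def scaled_config(factor: float = 0.25, n_variants: int = 2000,
                  n_shared: int = 25, n_focal_extra: int = 100) -> SimConfig:
    """A runtime-scaled variant of the default conditions.

    Cohort case/control counts are multiplied by ``factor`` (trial cohort
    kept at full size) and the variant panel shrunk; every structural
    parameter (trait counts, separability, prevalence) is unchanged.
    """
    base = SimConfig()
    cohorts = tuple(
        c if c.role == "trial"
        else replace(c, n_cases=int(c.n_cases * factor),
                     n_controls=int(c.n_controls * factor))
        for c in base.cohorts
    )
    return replace(base, cohorts=cohorts, n_variants=n_variants,
                   n_shared=n_shared, n_focal_extra=n_focal_extra)


@dataclass
class TruthBundle:
    """Ground truth for one simulated run."""

    config: SimConfig
    variant_ids: list[str]
    freqs: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray
    beta: dict  # trait_id (incl. focal) -> (M,) true effect vector
    blocks: dict  # trait_id -> np.ndarray of variant indices
    comorbid: dict  # trait_id -> bool
    burden_mean: dict  # trait_id -> population mean of genotype . beta
    burden_sd: dict  # trait_id -> population SD of genotype . beta
    subtype_label: dict = field(default_factory=dict)  # cohort -> Series (cases)
    subtype_drawn: dict = field(default_factory=dict)

    def class_effect_matrix(self) -> pd.DataFrame:
        rows = {
            o.outcome_id: list(o.class_effects) for o in self.config.outcomes
        }
        return pd.DataFrame(rows).T


def _child_rng(seed: int, *path: int) -> np.random.Generator:
    """Independent, reproducible stream for one component of the simulation."""
    return np.random.default_rng(np.random.SeedSequence([seed, *path]))


def _mills_ratio(prevalence: float) -> float:
    z = stats.norm.isf(prevalence)
    return stats.norm.pdf(z) / prevalence


def _build_truth(config: SimConfig, rng: np.random.Generator) -> TruthBundle:
    M = config.n_variants
    variant_ids = [f"rs{i + 1:06d}" for i in range(M)]
    freqs = rng.uniform(*config.maf_range, size=M)

    n_pal = int(round(config.palindromic_rate * M))
    pal_idx = rng.choice(M, size=n_pal, replace=False)
    pair_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=M)
    counted = np.array([_NONPALINDROMIC_PAIRS[c][0] for c in pair_choice], dtype=object)
    other = np.array([_NONPALINDROMIC_PAIRS[c][1] for c in pair_choice], dtype=object)
    pal_pick = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n_pal)
    for i, c in zip(pal_idx, pal_pick):
        counted[i], other[i] = _PALINDROMIC_PAIRS[c]

    blocks: dict[str, np.ndarray] = {}
    beta: dict[str, np.ndarray] = {}
    cursor = 0
    focal_support: list[int] = []
    for t, trait in enumerate(config.trait_ids):
        idx = np.arange(cursor, cursor + config.n_shared)
        cursor += config.n_shared
        blocks[trait] = idx
        b = np.zeros(M)
        b[idx] = rng.normal(0.0, config.effect_sd, size=config.n_shared)
        beta[trait] = b
        if trait in config.comorbid_traits:
            focal_support.extend(idx)
    extra = np.arange(cursor, cursor + config.n_focal_extra)
    focal_support.extend(extra)
    focal_idx = np.array(sorted(focal_support))
    blocks[FOCAL_TRAIT] = focal_idx
    b = np.zeros(M)
    b[focal_idx] = rng.normal(0.0, config.effect_sd, size=len(focal_idx))
    beta[FOCAL_TRAIT] = b

    burden_mean, burden_sd = {}, {}
    for trait, bvec in beta.items():
        burden_mean[trait] = float(2.0 * (freqs * bvec).sum())
        burden_sd[trait] = float(
            np.sqrt((2.0 * freqs * (1.0 - freqs) * bvec**2).sum())
        )

    comorbid = {t: t in config.comorbid_traits for t in config.trait_ids}
    return TruthBundle(
        config=config,
        variant_ids=variant_ids,
        freqs=freqs,
        counted_allele=counted.astype(str),
        other_allele=other.astype(str),
        beta=beta,
        blocks=blocks,
        comorbid=comorbid,
        burden_mean=burden_mean,
        burden_sd=burden_sd,
    )


def _case_tilt_logits(truth: TruthBundle) -> np.ndarray:
    """Per-subtype logit shifts over all variants: (n_subtypes, M)."""
    cfg = truth.config
    M = cfg.n_variants
    lam = _mills_ratio(cfg.prevalence)
    focal_sd = truth.burden_sd[FOCAL_TRAIT]
    shifts = np.zeros((cfg.n_subtypes, M))
    if focal_sd > 0:
        shifts += (lam / focal_sd) * truth.beta[FOCAL_TRAIT][None, :]
    for trait in cfg.comorbid_traits:
        u = cfg.subtype_of_trait(trait)
        sd = truth.burden_sd[trait]
        if sd > 0:
            theta = cfg.trait_direction(trait) * cfg.subtype_separation / sd
            shifts[u] += theta * truth.beta[trait]
    return shifts


def _simulate_cohort(
    spec: CohortSpec, truth: TruthBundle, rng: np.random.Generator
) -> GenotypeDataset:
    cfg = truth.config
    M = cfg.n_variants
    n = spec.n_cases + spec.n_controls
    f = truth.freqs

    dosage = rng.binomial(2, f[None, :], size=(n, M)).astype(np.float32)

    subtype = rng.integers(0, cfg.n_subtypes, size=spec.n_cases)
    shifts = _case_tilt_logits(truth)
    causal = np.flatnonzero(np.abs(shifts).sum(axis=0) > 0)
    base_logit = logit(f[causal])
    for u in range(cfg.n_subtypes):
        rows = np.flatnonzero(subtype == u)
        if len(rows) == 0:
            continue
        f_tilt = expit(base_logit + shifts[u, causal])
        dosage[np.ix_(rows, causal)] = rng.binomial(
            2, f_tilt[None, :], size=(len(rows), len(causal))
        ).astype(np.float32)

    sample_ids = [f"{spec.cohort_id}_{i + 1:05d}" for i in range(n)]
    phenotype = pd.Series(
        ["case"] * spec.n_cases + ["control"] * spec.n_controls,
        index=pd.Index(sample_ids, name="sample_id"),
    )
    covars = pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], size=n, p=[0.74, 0.26]),
            "age": np.round(rng.normal(40.0, 11.0, size=n), 1),
        },
        index=phenotype.index,
    )
    if spec.role == "trial":
        drugs = ["perphenazine", "olanzapine", "quetiapine", "risperidone", "ziprasidone"]
        covars["drug"] = rng.choice(drugs, size=n)

    # recorded subtype label: argmax over subtypes of the realized shared
    # genetic contribution (standardized, direction-aligned)
    case_ids = sample_ids[: spec.n_cases]
    contrib = np.zeros((spec.n_cases, cfg.n_subtypes))
    case_dos = dosage[: spec.n_cases].astype(np.float64)
    for trait in cfg.comorbid_traits:
        u = cfg.subtype_of_trait(trait)
        idx = truth.blocks[trait]
        b = truth.beta[trait][idx]
        burden = case_dos[:, idx] @ b
        z = (burden - truth.burden_mean[trait]) / truth.burden_sd[trait]
        contrib[:, u] += cfg.trait_direction(trait) * z
    label = contrib.argmax(axis=1)
    truth.subtype_label[spec.cohort_id] = pd.Series(
        label, index=pd.Index(case_ids, name="sample_id")
    )
    truth.subtype_drawn[spec.cohort_id] = pd.Series(
        subtype, index=pd.Index(case_ids, name="sample_id")
    )

    return GenotypeDataset(
        cohort_id=spec.cohort_id,
        sample_ids=sample_ids,
        variant_ids=list(truth.variant_ids),
        counted_allele=truth.counted_allele,
        other_allele=truth.other_allele,
        dosage=dosage,
        phenotype=phenotype,
        covariates=covars,
    )


def simulate_genomes(
    config: SimConfig, seed: int
) -> tuple[dict[str, GenotypeDataset], TruthBundle]:
    """Simulate genotypes for every cohort plus the ground-truth bundle.

    Fully deterministic under (config, seed).
    """
    truth = _build_truth(config, _child_rng(seed, 0))
    cohorts: dict[str, GenotypeDataset] = {}
    for i, spec in enumerate(config.cohorts):
        cohorts[spec.cohort_id] = _simulate_cohort(spec, truth, _child_rng(seed, 1, i))
    return cohorts, truth


def emit_summary_stats(
    truth: TruthBundle, seed: int
) -> dict[str, SummaryStatsTable]:
    """Reference-GWAS summary statistics per trait (focal disease included).

    Effects are estimated from an independent reference cohort, simulated
    at the sufficient-statistic level: beta_hat ~ N(beta, se^2) with
    se = 1/sqrt(2 f (1-f) n_eff); n_eff is the reference size for
    quantitative traits and its balanced case/control equivalent
    (n/4 on the log-odds information scale) for binary traits.  A small
    fraction of rows is reported on the opposite allele (with the effect
    sign flipped accordingly) to exercise downstream harmonization.
    """
    cfg = truth.config
    f = truth.freqs
    out: dict[str, SummaryStatsTable] = {}
    traits = [FOCAL_TRAIT] + cfg.trait_ids
    for i, trait in enumerate(traits):
        rng = _child_rng(seed, 2, i)
        trait_type = cfg.trait_type(trait)
        n_eff = cfg.reference_n * (0.25 if trait_type == "binary" else 1.0)
        se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_eff)
        bhat = truth.beta[trait] + rng.normal(0.0, se)
        p = 2.0 * stats.norm.sf(np.abs(bhat) / se)
        p = np.clip(p, np.finfo(float).tiny, 1.0)

        swap = rng.random(cfg.n_variants) < cfg.swap_rate
        ea = np.where(swap, truth.other_allele, truth.counted_allele)
        oa = np.where(swap, truth.counted_allele, truth.other_allele)
        bhat = np.where(swap, -bhat, bhat)
        effect = np.exp(bhat) if trait_type == "binary" else bhat

        records = pd.DataFrame(
            {
                "effect_allele": ea,
                "other_allele": oa,
                "effect": effect,
                "p": p,
            },
            index=pd.Index(truth.variant_ids, name="variant_id"),
        )
        out[trait] = SummaryStatsTable(trait, trait_type, records)
    return out


def simulate_outcomes(
    trial_geno: GenotypeDataset, truth: TruthBundle, seed: int
) -> pd.DataFrame:
    """Pre/post clinical outcomes for the trial cohort (long format).

    Baseline = class baseline + Gaussian noise; the post-treatment value
    realizes the class treatment effect plus change noise, on the sign
    convention of each outcome family.  Follow-up values are missing
    completely at random at 1 - followup_rate.
    """
    cfg = truth.config
    labels = truth.subtype_label.get(trial_geno.cohort_id)
    if labels is None:
        raise SimulationError(
            f"no subtype labels recorded for cohort {trial_geno.cohort_id!r}"
        )
    case_ids = list(labels.index)
    sub = labels.to_numpy()
    rows: list[dict] = []
    for i, spec in enumerate(cfg.outcomes):
        rng = _child_rng(seed, 3, i)
        shift = np.zeros(cfg.n_subtypes)
        if spec.baseline_class_shift is not None:
            shift = np.asarray(spec.baseline_class_shift)
        baseline = (
            spec.baseline_mean
            + shift[sub]
            + rng.normal(0.0, spec.baseline_sd, size=len(case_ids))
        )
        if spec.family == "symptom":
            baseline = np.maximum(baseline, 0.0)
        reported = np.asarray(spec.class_effects)[sub] + rng.normal(
            0.0, spec.change_sd, size=len(case_ids)
        )
        post = (
            baseline - reported
            if spec.direction == "pre_minus_post"
            else baseline + reported
        )
        if spec.family == "symptom":
            post = np.maximum(post, 0.0)
        observed = rng.random(len(case_ids)) < spec.followup_rate
        for j, sid in enumerate(case_ids):
            rows.append(
                {"sample_id": sid, "visit": "baseline",
                 "outcome_id": spec.outcome_id, "value": baseline[j]}
            )
            if observed[j]:
                rows.append(
                    {"sample_id": sid, "visit": spec.visit_post,
                     "outcome_id": spec.outcome_id, "value": post[j]}
                )
    return pd.DataFrame(rows)


def simulate_prs_blobs(
    n_cases: int,
    n_traits: int,
    n_subtypes: int,
    separation: float,
    seed: int,
    cohort_id: str = "blobs",
) -> tuple[PRSMatrix, np.ndarray]:
    """Directly planted PRS blobs: subtype centroids separated by
    ``separation`` x the unit within-cluster SD along subtype-specific
    coordinates.  Used to study the clustering stage in isolation."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_subtypes, size=n_cases)
    centroids = np.zeros((n_subtypes, n_traits))
    for u in range(n_subtypes):
        coords = [t for t in range(n_traits) if t % n_subtypes == u]
        centroids[u, coords] = separation / np.sqrt(max(len(coords), 1))
    X = centroids[labels] + rng.normal(size=(n_cases, n_traits))
    scores = pd.DataFrame(
        X,
        index=pd.Index([f"case_{i:05d}" for i in range(n_cases)], name="sample_id"),
        columns=[f"trait{t + 1:02d}" for t in range(n_traits)],
    )
    X = (scores - scores.mean()) / scores.std(ddof=1)
    return PRSMatrix(cohort_id, X, standardized=True), labels
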
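"""Stage orchestration: simulate -> prs -> screen -> cluster -> associate.

Two entry points:

* :func:`run_pipeline` runs all stages in memory on a single (config, seed)
  and returns every intermediate object — the workhorse for analyses and
  for recovery experiments.
* :func:`run_stage` is the file-based interface behind the CLI: each stage
  reads its upstream artifacts from the output directory, writes its own
  as plain TSV/JSON, and updates the run manifest.  A missing upstream
  artifact is fatal and names the stage that produces it.

All randomness flows from the single top-level seed; identical
(config, seed) reruns produce byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ClassAssignment,
    ClusterVote,
    LinkageTree,
    assign_classes,
    cross_cohort_consistency,
    hierarchical_cluster,
    refine_split,
    to_newick,
    validity_vote,
)
from .indices import INDEX_NAMES, PANEL_VERSION
from .io import GenotypeDataset, read_genotypes, read_phenotypes, write_dosage_tsv, harmonize
from .outcomes import (
    OutcomeContrast,
    baseline_class_model,
    class_summary,
    per_class_report,
)
from .prs import (
    PRSMatrix,
    build_prs_matrix,
    build_weights,
    read_prs_matrix,
    select_joint_markers,
    select_single_markers,
    standardize,
    write_prs_matrix,
    write_weights,
)
from .screen import run_screen, selected_traits
from .simulate import (
    FOCAL_TRAIT,
    CohortSpec,
    SimConfig,
    TruthBundle,
    emit_summary_stats,
    simulate_genomes,
    simulate_outcomes,
)
from .io import SummaryStatsTable, write_summary_stats, read_summary_stats

STAGES = ("simulate", "prs", "screen", "cluster", "associate", "report")

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis settings for one reproducible run."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 1
    p_marker: float = 0.05  # joint per-variant threshold for PRS markers
    p_screen: float = 0.15  # cross-cohort trait-screening threshold
    linkage: str = "ward"
    k_range: tuple[int, int] = (2, 10)
    missing_policy: str = "mean_impute"
    trial_refine: tuple[str, int] | None = None  # (class label, sub_k)

    def settings_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["index_panel"] = PANEL_VERSION
        d["focal_marker_rule"] = "single_threshold"
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.settings_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path, seed: int | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus CLI overrides."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    if "cohorts" in sim_raw:
        sim_raw["cohorts"] = tuple(
            CohortSpec(
                c["cohort_id"], int(c["n_cases"]), int(c.get("n_controls", 0)),
                c.get("role", "discovery"),
            )
            for c in sim_raw["cohorts"]
        )
    sim = SimConfig(**sim_raw)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if seed is not None:
        raw["seed"] = seed
    if "k_range" in raw and isinstance(raw["k_range"], str):
        lo, hi = raw["k_range"].split(":")
        raw["k_range"] = (int(lo), int(hi))
    if "trial_refine" in raw and raw["trial_refine"] is not None:
        cls, sub_k = raw["trial_refine"]
        raw["trial_refine"] = (str(cls), int(sub_k))
    return PipelineConfig(sim=sim, **raw)


# ---------------------------------------------------------------------------
# in-memory pipeline


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohorts: dict
    truth: TruthBundle
    sumstats: dict
    prs: dict  # cohort -> PRSMatrix (standardized, all candidate traits + focal)
    screen_table: pd.DataFrame
    selected: list
    trees: dict  # cohort -> LinkageTree (cases)
    case_prs: dict  # cohort -> PRSMatrix (cases, selected traits, re-standardized)
    votes: dict  # cohort -> ClusterVote
    trial_assignment: ClassAssignment
    outcomes: pd.DataFrame
    outcome_report: pd.DataFrame
    baseline_tables: dict
    summary: pd.DataFrame


def compute_prs_matrices(
    cohorts: dict[str, GenotypeDataset],
    sumstats: dict[str, SummaryStatsTable],
    p_marker: float = 0.05,
    missing_policy: str = "mean_impute",
) -> tuple[dict[str, PRSMatrix], dict[str, list]]:
    """Joint-threshold marker selection, harmonization and scoring.

    The focal disease uses the single-trait threshold; every candidate
    trait uses the joint rule (p <= p_marker in both the focal disease and
    the trait).  Returns standardized per-cohort PRS matrices and the
    selected-marker lists per trait.
    """
    focal = sumstats[FOCAL_TRAIT]
    selected_markers: dict[str, list] = {
        FOCAL_TRAIT: select_single_markers(focal, p_marker)
    }
    for trait, st in sumstats.items():
        if trait != FOCAL_TRAIT:
            selected_markers[trait] = select_joint_markers(focal, st, p_marker)

    prs_by_cohort: dict[str, PRSMatrix] = {}
    for cohort_id, geno in cohorts.items():
        weight_sets = []
        for trait, st in sumstats.items():
            hmap = harmonize(st, geno)
            usable = [v for v in selected_markers[trait] if v in hmap.index]
            weight_sets.append(build_weights(st, usable, hmap))
        prs_by_cohort[cohort_id] = build_prs_matrix(
            geno, weight_sets, missing_policy=missing_policy, standardized=True
        )
    return prs_by_cohort, selected_markers


def cluster_cases(
    prs: PRSMatrix,
    case_ids: list[str],
    traits: list[str],
    linkage: str = "ward",
    k_range: tuple[int, int] = (2, 10),
) -> tuple[PRSMatrix, LinkageTree, ClusterVote]:
    """Cluster the cases of one cohort on the selected-trait scores.

    Scores are re-standardized within the case subset so Euclidean
    distances weight each trait equally among the patients being
    clustered.
    """
    sub = PRSMatrix(prs.cohort_id, prs.scores.loc[case_ids, traits], standardized=False)
    sub = standardize(sub)
    tree = hierarchical_cluster(sub, linkage=linkage)
    vote = validity_vote(sub, tree, k_range=k_range)
    return sub, tree, vote


def outcome_contrasts(sim: SimConfig) -> list[OutcomeContrast]:
    return [
        OutcomeContrast(
            o.outcome_id, "baseline", o.visit_post, o.direction, o.family, o.family_size
        )
        for o in sim.outcomes
    ]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """End-to-end in-memory run on synthetic cohorts."""
    cohorts, truth = simulate_genomes(config.sim, config.seed)
    sumstats = emit_summary_stats(truth, config.seed)
    outcomes = simulate_outcomes(
        cohorts[_trial_id(config.sim)], truth, config.seed
    )

    prs, _markers = compute_prs_matrices(
        cohorts, sumstats, config.p_marker, config.missing_policy
    )

    discovery = [c.cohort_id for c in config.sim.cohorts if c.role == "discovery"]
    screen_table = run_screen(
        {c: prs[c] for c in discovery},
        {c: cohorts[c].phenotype for c in discovery},
        config.sim.trait_ids,
        p_threshold=config.p_screen,
    )
    chosen_traits = selected_traits(screen_table)
    cluster_traits = [FOCAL_TRAIT] + chosen_traits

    trees, votes, case_prs = {}, {}, {}
    for cohort_id, geno in cohorts.items():
        ids = [s for s, m in zip(geno.sample_ids, geno.case_mask()) if m]
        case_prs[cohort_id], trees[cohort_id], votes[cohort_id] = cluster_cases(
            prs[cohort_id], ids, cluster_traits, config.linkage, config.k_range
        )

    trial = _trial_id(config.sim)
    assignment = assign_classes(trees[trial], votes[trial].chosen_k)
    if config.trial_refine is not None:
        cls, sub_k = config.trial_refine
        assignment = refine_split(trees[trial], assignment, cls, sub_k)

    report = per_class_report(outcomes, assignment, outcome_contrasts(config.sim))
    covars = cohorts[trial].covariates.loc[assignment.labels.index]
    baseline_tables = {}
    base = outcomes[outcomes["visit"] == "baseline"]
    for outcome_id in base["outcome_id"].unique():
        y = base[base["outcome_id"] == outcome_id].set_index("sample_id")["value"]
        y.name = outcome_id
        baseline_tables[outcome_id] = baseline_class_model(
            y, assignment, covariates=covars, family="linear"
        )
    summary = class_summary(report, assignment)

    return PipelineResult(
        config=config,
        cohorts=cohorts,
        truth=truth,
        sumstats=sumstats,
        prs=prs,
        screen_table=screen_table,
        selected=chosen_traits,
        trees=trees,
        case_prs=case_prs,
        votes=votes,
        trial_assignment=assignment,
        outcomes=outcomes,
        outcome_report=report,
        baseline_tables=baseline_tables,
        summary=summary,
    )


def _trial_id(sim: SimConfig) -> str:
    for c in sim.cohorts:
        if c.role == "trial":
            return c.cohort_id
    raise PipelineError("config defines no trial cohort")


def recovery_metrics(result: PipelineResult) -> dict:
    """Measure recovery of the planted structure for one pipeline run."""
    from sklearn.metrics import adjusted_rand_score

    cfg = result.config
    truth = result.truth
    true_traits = {t for t, flag in truth.comorbid.items() if flag}
    sel = set(result.selected)
    trial = _trial_id(cfg.sim)
    labels_true = truth.subtype_label[trial]
    cut_true_k = assign_classes(result.trees[trial], cfg.sim.n_subtypes)
    ari_true_k = adjusted_rand_score(
        labels_true.to_numpy(), cut_true_k.labels.reindex(labels_true.index).to_numpy()
    )
    ari_chosen = adjusted_rand_score(
        labels_true.to_numpy(),
        result.trial_assignment.labels.reindex(labels_true.index).to_numpy(),
    )
    discovery = [c.cohort_id for c in cfg.sim.cohorts if c.role == "discovery"]
    return {
        "n_true_traits": len(true_traits),
        "n_recovered": len(sel & true_traits),
        "n_false_selected": len(sel - true_traits),
        "chosen_k": {c: result.votes[c].chosen_k for c in discovery + [trial]},
        "endorsements": {c: result.votes[c].endorsements for c in discovery + [trial]},
        "ari_at_true_k": float(ari_true_k),
        "ari_at_chosen_k": float(ari_chosen),
    }


# ---------------------------------------------------------------------------
# file-based stages (CLI)


def _manifest_path(out: Path) -> Path:
    return out / "manifest.json"


def _update_manifest(out: Path, config: PipelineConfig, stage: str, files: list[str]):
    path = _manifest_path(out)
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest.setdefault("config_hash", config.config_hash())
    manifest.setdefault("seed", config.seed)
    manifest.setdefault("settings", config.settings_dict())
    manifest.setdefault("version", __version__)
    digests = manifest.setdefault("file_digests", {})
    for name in files:
        digests[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()[:16]
    stages = manifest.setdefault("stages", [])
    if stage not in stages:
        stages.append(stage)
    if manifest["config_hash"] != config.config_hash():
        raise PipelineError(
            "config/manifest mismatch: output directory was produced by a "
            "different configuration (use a fresh --out or --force)"
        )
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _require(out: Path, name: str, producer: str) -> Path:
    p = out / name
    if not p.exists():
        raise PipelineError(
            f"missing upstream artifact {name!r}: run the {producer!r} stage first"
        )
    return p


def _stage_simulate(config: PipelineConfig, out: Path) -> list[str]:
    cohorts, truth = simulate_genomes(config.sim, config.seed)
    sumstats = emit_summary_stats(truth, config.seed)
    outcomes = simulate_outcomes(cohorts[_trial_id(config.sim)], truth, config.seed)
    files = []
    for cid, geno in cohorts.items():
        write_dosage_tsv(geno, out / f"genotypes_{cid}.dosage.tsv")
        pheno = pd.concat([geno.phenotype.rename("phenotype"), geno.covariates], axis=1)
        pheno.to_csv(out / f"phenotype_{cid}.tsv", sep="\t")
        files += [f"genotypes_{cid}.dosage.tsv", f"phenotype_{cid}.tsv"]
    for trait, st in sumstats.items():
        write_summary_stats(st, out / f"sumstats_{trait}.tsv")
        files.append(f"sumstats_{trait}.tsv")
    outcomes.to_csv(out / "outcomes_trial.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT)
    files.append("outcomes_trial.tsv")
    truth_small = {
        "comorbid": truth.comorbid,
        "subtype_label": {c: s.to_dict() for c, s in truth.subtype_label.items()},
        "n_subtypes": config.sim.n_subtypes,
    }
    (out / "truth.json").write_text(json.dumps(truth_small, indent=2, sort_keys=True))
    files.append("truth.json")
    return files


def _load_cohort(config: PipelineConfig, out: Path, cid: str) -> GenotypeDataset:
    gpath = _require(out, f"genotypes_{cid}.dosage.tsv", "simulate")
    ppath = _require(out, f"phenotype_{cid}.tsv", "simulate")
    geno = read_genotypes(gpath, "dosage_tsv", cohort_id=cid)
    pheno = read_phenotypes(ppath)
    geno.phenotype = pheno["phenotype"]
    geno.covariates = pheno.drop(columns=["phenotype"])
    return geno


def _stage_prs(config: PipelineConfig, out: Path) -> list[str]:
    cohort_ids = [c.cohort_id for c in config.sim.cohorts]
    cohorts = {cid: _load_cohort(config, out, cid) for cid in cohort_ids}
    traits = [FOCAL_TRAIT] + config.sim.trait_ids
    sumstats = {}
    for trait in traits:
        path = _require(out, f"sumstats_{trait}.tsv", "simulate")
        sumstats[trait] = read_summary_stats(
            path, trait, config.sim.trait_type(trait)
        )
    prs, markers = compute_prs_matrices(
        cohorts, sumstats, config.p_marker, config.missing_policy
    )
    files = []
    for cid, mat in prs.items():
        write_prs_matrix(mat, out / f"prs_{cid}.tsv")
        files.append(f"prs_{cid}.tsv")
    first = cohorts[cohort_ids[0]]
    for trait in traits:
        hmap = harmonize(sumstats[trait], first)
        usable = [v for v in markers[trait] if v in hmap.index]
        ws = build_weights(sumstats[trait], usable, hmap)
        write_weights(ws, first, out / f"weights_{trait}.tsv")
        files.append(f"weights_{trait}.tsv")
    return files


def _stage_screen(config: PipelineConfig, out: Path) -> list[str]:
    discovery = [c.cohort_id for c in config.sim.cohorts if c.role == "discovery"]
    prs, pheno = {}, {}
    for cid in discovery:
        prs[cid] = read_prs_matrix(_require(out, f"prs_{cid}.tsv", "prs"))
        tab = read_phenotypes(_require(out, f"phenotype_{cid}.tsv", "simulate"))
        pheno[cid] = tab["phenotype"]
    table = run_screen(prs, pheno, config.sim.trait_ids, p_threshold=config.p_screen)
    table.to_csv(out / "screen_report.tsv", sep="\t", float_format=FLOAT_FMT)
    (out / "selected_traits.txt").write_text(
        "\n".join(selected_traits(table)) + "\n"
    )
    return ["screen_report.tsv", "selected_traits.txt"]


def _stage_cluster(config: PipelineConfig, out: Path) -> list[str]:
    for spec in config.sim.cohorts:  # earliest upstream first
        _require(out, f"prs_{spec.cohort_id}.tsv", "prs")
    sel_path = _require(out, "selected_traits.txt", "screen")
    chosen = [t for t in sel_path.read_text().split() if t]
    traits = [FOCAL_TRAIT] + chosen
    files = []
    votes = {}
    for spec in config.sim.cohorts:
        cid = spec.cohort_id
        prs = read_prs_matrix(_require(out, f"prs_{cid}.tsv", "prs"))
        pheno = read_phenotypes(_require(out, f"phenotype_{cid}.tsv", "simulate"))
        case_ids = list(pheno.index[pheno["phenotype"] == "case"])
        sub, tree, vote = cluster_cases(
            prs, case_ids, traits, config.linkage, config.k_range
        )
        votes[cid] = vote
        assign = assign_classes(tree, vote.chosen_k)
        if spec.role == "trial" and config.trial_refine is not None:
            assign = refine_split(tree, assign, *config.trial_refine)
        pd.DataFrame(
            {"class": assign.labels}
        ).to_csv(out / f"labels_{cid}.tsv", sep="\t")
        vote_df = pd.DataFrame(
            [{"index": n, "best_k": vote.best_k.get(n)} for n in INDEX_NAMES]
        )
        vote_df.to_csv(out / f"votes_{cid}.tsv", sep="\t", index=False)
        (out / f"dendrogram_{cid}.nwk").write_text(to_newick(tree) + "\n")
        files += [f"labels_{cid}.tsv", f"votes_{cid}.tsv", f"dendrogram_{cid}.nwk"]
        summary = {
            "chosen_k": vote.chosen_k,
            "endorsements": vote.endorsements,
            "tally": {str(k): v for k, v in vote.tally.items()},
            "panel_version": vote.panel_version,
            "linkage": config.linkage,
        }
        (out / f"vote_summary_{cid}.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        files.append(f"vote_summary_{cid}.json")
    discovery = [c.cohort_id for c in config.sim.cohorts if c.role == "discovery"]
    if len(discovery) >= 2:
        rep = cross_cohort_consistency(votes[discovery[0]], votes[discovery[1]])
        (out / "consistency_discovery.json").write_text(
            json.dumps(dataclasses.asdict(rep), indent=2, sort_keys=True, default=str)
            + "\n"
        )
        files.append("consistency_discovery.json")
    return files


def _stage_associate(config: PipelineConfig, out: Path) -> list[str]:
    trial = _trial_id(config.sim)
    labels = pd.read_csv(
        _require(out, f"labels_{trial}.tsv", "cluster"), sep="\t", index_col=0
    )["class"]
    assignment = ClassAssignment(labels=labels)
    outcomes = pd.read_csv(
        _require(out, "outcomes_trial.tsv", "simulate"), sep="\t",
        dtype={"sample_id": str},
    )
    pheno = read_phenotypes(_require(out, f"phenotype_{trial}.tsv", "simulate"))
    covars = pheno.drop(columns=["phenotype"]).loc[labels.index]
    report = per_class_report(outcomes, assignment, outcome_contrasts(config.sim))
    report.to_csv(out / "outcome_report.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)
    base = outcomes[outcomes["visit"] == "baseline"]
    rows = []
    for outcome_id in base["outcome_id"].unique():
        y = base[base["outcome_id"] == outcome_id].set_index("sample_id")["value"]
        y.name = outcome_id
        res = baseline_class_model(y, assignment, covariates=covars, family="linear")
        for cls, r in res.table.iterrows():
            rows.append(
                {"outcome_id": outcome_id, "class": cls, **r.to_dict(),
                 "reference": res.reference_class}
            )
    pd.DataFrame(rows).to_csv(out / "baseline_assoc.tsv", sep="\t", index=False,
                              float_format=FLOAT_FMT)
    class_summary(report, assignment).to_csv(
        out / "class_summary.tsv", sep="\t", float_format=FLOAT_FMT
    )
    return ["outcome_report.tsv", "baseline_assoc.tsv", "class_summary.tsv"]


def _stage_report(config: PipelineConfig, out: Path) -> list[str]:
    _require(out, "class_summary.tsv", "associate")
    summary = {"stages_complete": True, "config_hash": config.config_hash()}
    for spec in config.sim.cohorts:
        vs = out / f"vote_summary_{spec.cohort_id}.json"
        if vs.exists():
            summary[f"vote_{spec.cohort_id}"] = json.loads(vs.read_text())
    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return ["run_summary.json"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "prs": _stage_prs,
    "screen": _stage_screen,
    "cluster": _stage_cluster,
    "associate": _stage_associate,
    "report": _stage_report,
}


def run_stage(stage: str, config: PipelineConfig, out_dir) -> list[str]:
    """Run one file-based stage; returns the files it wrote."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; stages are {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = _STAGE_FN[stage](config, out)
    _update_manifest(out, config, stage, files)
    return files
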
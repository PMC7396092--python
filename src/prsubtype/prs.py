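"""Joint-threshold marker selection and weighted polygenic scoring.

Markers are selected when they reach the significance threshold in *both*
the focal disease and the candidate trait (default p <= 0.05 in each).
Weights are ln(OR) for binary traits and beta for quantitative traits.
Scores are the weighted sum of counted-allele dosages; harmonization flips
are applied to the dosage (2 - d), never to the weight, so constant offsets
are absorbed by the per-cohort standardization applied before clustering
and regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeDataset, SummaryStatsTable


class PRSError(ValueError):
    pass


@dataclass
class WeightSet:
    """Per-variant scoring weights for one trait, after harmonization."""

    trait_id: str
    entries: pd.DataFrame  # index variant_id; cols: weight (float), flip (bool)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PRSMatrix:
    """Samples x traits polygenic scores for one cohort."""

    cohort_id: str
    scores: pd.DataFrame  # index sample_id, columns trait_id
    standardized: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(float)


def select_joint_markers(
    focal_stats: SummaryStatsTable,
    trait_stats: SummaryStatsTable,
    alpha: float = 0.05,
) -> list[str]:
    """Variants with p <= alpha in both the focal disease and the trait.

    Returns a sorted list.  An empty result is a warning, not an error: the
    downstream score is a degenerate zero-marker score.
    """
    if not 0 < alpha <= 1:
        raise PRSError(f"alpha must be in (0, 1], got {alpha}")
    shared = focal_stats.variant_ids.intersection(trait_stats.variant_ids)
    keep = shared[
        (focal_stats.records.loc[shared, "p"] <= alpha)
        & (trait_stats.records.loc[shared, "p"] <= alpha)
    ]
    if len(keep) == 0:
        warnings.warn(
            f"no jointly significant markers for trait {trait_stats.trait_id!r} "
            f"at alpha={alpha}",
            stacklevel=2,
        )
    return sorted(keep)


def select_single_markers(stats: SummaryStatsTable, alpha: float = 0.05) -> list[str]:
    """Single-trait threshold selection (used for the focal-disease score)."""
    if not 0 < alpha <= 1:
        raise PRSError(f"alpha must be in (0, 1], got {alpha}")
    return sorted(stats.variant_ids[stats.records["p"] <= alpha])


def build_weights(
    trait_stats: SummaryStatsTable,
    selected: list[str],
    hmap: pd.DataFrame,
) -> WeightSet:
    """Turn selected markers into scoring weights.

    weight = ln(OR) for binary traits, beta for quantitative.  Variants with
    a ``drop`` harmonization action (palindromic or allele mismatch) are
    excluded; ``flip_weight`` actions are recorded for the scorer, which
    flips the dosage rather than the weight.
    """
    sel = pd.Index(selected)
    missing = sel.difference(trait_stats.variant_ids)
    if len(missing):
        raise PRSError(f"selected variants absent from stats: {list(missing)[:5]}")
    hm = hmap.reindex(sel)
    if hm["action"].isna().any():
        raise PRSError("harmonization map does not cover all selected variants")
    keep = hm.index[hm["action"] != "drop"]
    eff = trait_stats.records.loc[keep, "effect"].to_numpy(float)
    if trait_stats.trait_type == "binary":
        if (eff <= 0).any():
            raise PRSError(f"non-positive OR in trait {trait_stats.trait_id!r}")
        weight = np.log(eff)
    else:
        weight = eff
    entries = pd.DataFrame(
        {"weight": weight, "flip": (hm.loc[keep, "action"] == "flip_weight").to_numpy()},
        index=keep,
    )
    return WeightSet(trait_stats.trait_id, entries)


def score_samples(
    geno: GenotypeDataset,
    weights: WeightSet,
    missing_policy: str = "mean_impute",
) -> np.ndarray:
    """Per-sample weighted dosage sum: score_i = sum_j w_j * d_ij.

    Flip-action dosages are replaced by 2-d before weighting.  Missing
    dosages are replaced by the variant's cohort mean (``mean_impute``) or
    the observed weighted sum is rescaled by total/observed marker count
    (``omit_rescale``).
    """
    if missing_policy not in ("mean_impute", "omit_rescale"):
        raise PRSError(f"unknown missing_policy {missing_policy!r}")
    if len(weights) == 0:
        warnings.warn(
            f"zero-marker weight set for trait {weights.trait_id!r}; scores are 0",
            stacklevel=2,
        )
        return np.zeros(geno.n_samples)

    col_of = {v: j for j, v in enumerate(geno.variant_ids)}
    try:
        idx = np.array([col_of[v] for v in weights.entries.index])
    except KeyError as e:
        raise PRSError(f"weight variant {e.args[0]!r} not in genotype dataset") from None

    D = geno.dosage[:, idx].astype(float, copy=True)
    flip = weights.entries["flip"].to_numpy()
    D[:, flip] = 2.0 - D[:, flip]
    w = weights.entries["weight"].to_numpy(float)

    miss = np.isnan(D)
    if missing_policy == "mean_impute":
        if miss.any():
            col_mean = np.nanmean(D, axis=0)
            # a fully missing column has no cohort mean to impute from
            if np.isnan(col_mean).any():
                raise PRSError("variant with all dosages missing cannot be mean-imputed")
            D = np.where(miss, col_mean[None, :], D)
        return D @ w
    # omit_rescale
    observed = (~miss).sum(axis=1)
    if (observed == 0).any():
        raise PRSError("sample with all marker dosages missing")
    score = np.where(miss, 0.0, D) @ w
    return score * (len(w) / observed)


def standardize(prs: PRSMatrix) -> PRSMatrix:
    """Per-column z-scores within the cohort (ddof=1).

    A zero-variance column is fatal and names the trait.  Idempotent up to
    floating-point error.
    """
    X = prs.scores
    if len(X) < 2:
        raise PRSError("standardization needs at least 2 samples")
    sd = X.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise PRSError(f"zero-variance PRS column(s): {list(zero.index)}")
    Z = (X - X.mean()) / sd
    return PRSMatrix(prs.cohort_id, Z, standardized=True)


def build_prs_matrix(
    geno: GenotypeDataset,
    weight_sets: list[WeightSet],
    missing_policy: str = "mean_impute",
    standardized: bool = True,
) -> PRSMatrix:
    """Score a cohort for several traits and optionally standardize."""
    cols = {
        ws.trait_id: score_samples(geno, ws, missing_policy) for ws in weight_sets
    }
    prs = PRSMatrix(
        geno.cohort_id,
        pd.DataFrame(cols, index=pd.Index(geno.sample_ids, name="sample_id")),
    )
    return standardize(prs) if standardized else prs


def write_prs_matrix(prs: PRSMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#cohort\t{prs.cohort_id}\t standardized={prs.standardized}\n")
        prs.scores.to_csv(fh, sep="\t", float_format="%.10g")


def read_prs_matrix(path) -> PRSMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "#cohort":
            raise PRSError(f"{path}: missing '#cohort' header line")
        cohort_id = header[1]
        standardized = "standardized=True" in (header[2] if len(header) > 2 else "")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return PRSMatrix(cohort_id, df, standardized=standardized)


def write_weights(ws: WeightSet, geno: GenotypeDataset, path) -> None:
    """PLINK --score compatible column order: variant, counted allele, weight."""
    col_of = {v: j for j, v in enumerate(geno.variant_ids)}
    with open(path, "w") as fh:
        fh.write("SNP\tA1\tWEIGHT\n")
        for vid, row in ws.entries.iterrows():
            j = col_of[vid]
            allele = (
                geno.other_allele[j] if row["flip"] else geno.counted_allele[j]
            )
            fh.write(f"{vid}\t{allele}\t{row['weight']:.10g}\n")
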
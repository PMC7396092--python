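"""Readers, writers and allele harmonization for GWAS summary statistics,
genotype dosages and phenotype tables.

Summary statistics arrive as delimited text with configurable column names
(SNP, A1, A2, OR/BETA, P).  Genotypes are accepted either as VCF (DS field
when present, otherwise GT allele counts) or as a plain tab-separated dosage
dialect: two ``#``-prefixed metadata lines carrying the counted and other
allele per variant, then a header row of variant IDs with the sample ID in
the first column.  Missing dosages are kept as NaN at load time; imputation
is the scoring engine's policy, not the reader's.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
#: strand-ambiguous allele pairs, dropped during harmonization
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

MISSING_SENTINEL = "NA"


class SummaryStatsError(ValueError):
    """Fatal problem with a summary-statistics file."""


class GenotypeError(ValueError):
    """Fatal problem with a genotype file."""


@dataclass
class LoadReport:
    """Row-level accounting for a summary-statistics load."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: Counter = field(default_factory=Counter)


@dataclass
class SummaryStatsTable:
    """Per-variant association results for one trait.

    ``effect`` is an odds ratio for binary traits (OR > 0) and a regression
    beta for quantitative traits.  p-values lie in (0, 1]; variant IDs are
    unique; effect and other allele are single, distinct bases.
    """

    trait_id: str
    trait_type: str  # "binary" | "quantitative"
    records: pd.DataFrame  # index: variant_id; cols: effect_allele, other_allele, effect, p
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise SummaryStatsError(
                f"trait_type must be 'binary' or 'quantitative', got {self.trait_type!r}"
            )

    @property
    def variant_ids(self) -> pd.Index:
        return self.records.index

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GenotypeDataset:
    """Samples x variants dosage matrix with phenotype and covariates.

    Dosages count copies of the per-variant ``counted_allele`` and lie in
    [0, 2]; missing genotypes are NaN.  ``phenotype`` holds
    'case'/'control'/'unknown' per sample.
    """

    cohort_id: str
    sample_ids: list[str]
    variant_ids: list[str]
    counted_allele: np.ndarray  # (m,) of single-char str
    other_allele: np.ndarray
    dosage: np.ndarray  # (n, m) float, NaN = missing
    phenotype: pd.Series | None = None  # index sample_id, values case/control/unknown
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise GenotypeError("dosage shape does not match sample/variant IDs")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample IDs")
        if len(set(self.variant_ids)) != m:
            raise GenotypeError("duplicate variant IDs")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"dosage outside [0,2] at sample {self.sample_ids[i]!r}, "
                f"variant {self.variant_ids[j]!r}: {self.dosage[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def case_mask(self) -> np.ndarray:
        if self.phenotype is None:
            raise GenotypeError(f"cohort {self.cohort_id!r} has no phenotype attached")
        return (self.phenotype.reindex(self.sample_ids) == "case").to_numpy()

    def subset_samples(self, mask: np.ndarray) -> "GenotypeDataset":
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return GenotypeDataset(
            cohort_id=self.cohort_id,
            sample_ids=ids,
            variant_ids=list(self.variant_ids),
            counted_allele=self.counted_allele,
            other_allele=self.other_allele,
            dosage=self.dosage[np.asarray(mask, bool)],
            phenotype=None if self.phenotype is None else self.phenotype.loc[ids],
            covariates=None if self.covariates is None else self.covariates.loc[ids],
        )


DEFAULT_COLUMNS = {
    "variant_id": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "effect": None,  # OR for binary, BETA for quantitative
    "p": "P",
}


def read_summary_stats(
    path,
    trait_id: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> SummaryStatsTable:
    """Read and validate a summary-statistics table.

    Rows violating the invariants (p outside (0,1], malformed or identical
    alleles, non-positive OR for binary traits, duplicate variant IDs) are
    dropped and counted in the load report.  A missing mapped column or an
    empty table after filtering is fatal.
    """
    cols = dict(DEFAULT_COLUMNS)
    if cols["effect"] is None:
        cols["effect"] = "OR" if trait_type == "binary" else "BETA"
    if column_map:
        cols.update(column_map)

    df = pd.read_csv(path, sep=delimiter, dtype={cols["variant_id"]: str})
    for key, name in cols.items():
        if name not in df.columns:
            raise SummaryStatsError(
                f"{path}: required column {name!r} (for {key}) not found"
            )

    report = LoadReport(n_read=len(df))
    out = pd.DataFrame(
        {
            "effect_allele": df[cols["effect_allele"]].astype(str).str.upper().to_numpy(),
            "other_allele": df[cols["other_allele"]].astype(str).str.upper().to_numpy(),
            "effect": pd.to_numeric(df[cols["effect"]], errors="coerce").to_numpy(),
            "p": pd.to_numeric(df[cols["p"]], errors="coerce").to_numpy(),
        },
        index=pd.Index(df[cols["variant_id"]].to_numpy(), name="variant_id"),
    )

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal out
        n = int(mask.sum())
        if n:
            report.reasons[reason] += n
            out = out[~mask]

    drop(~out["p"].gt(0) | out["p"].gt(1) | out["p"].isna(), "invalid_p")
    drop(
        ~out["effect_allele"].isin(VALID_BASES)
        | ~out["other_allele"].isin(VALID_BASES),
        "invalid_allele",
    )
    drop(out["effect_allele"] == out["other_allele"], "identical_alleles")
    drop(out["effect"].isna(), "missing_effect")
    if trait_type == "binary":
        drop(out["effect"] <= 0, "nonpositive_or")
    drop(pd.Series(out.index.duplicated(), index=out.index), "duplicate_variant")

    report.n_kept = len(out)
    report.n_dropped = report.n_read - report.n_kept
    if report.n_kept == 0:
        raise SummaryStatsError(f"{path}: no valid rows remain after filtering")
    return SummaryStatsTable(trait_id, trait_type, out, report)


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    effect_col = "OR" if table.trait_type == "binary" else "BETA"
    df = table.records.reset_index()
    df.columns = ["SNP", "A1", "A2", effect_col, "P"]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# genotype dosage TSV dialect


def write_dosage_tsv(geno: GenotypeDataset, path) -> None:
    """Write the dosage TSV dialect (bit-exact round trip via %.17g)."""
    with open(path, "w") as fh:
        fh.write("#counted_allele\t" + "\t".join(geno.counted_allele) + "\n")
        fh.write("#other_allele\t" + "\t".join(geno.other_allele) + "\n")
        fh.write("sample_id\t" + "\t".join(geno.variant_ids) + "\n")
        for i, sid in enumerate(geno.sample_ids):
            row = geno.dosage[i]
            cells = [
                MISSING_SENTINEL if np.isnan(v) else format(v, ".17g") for v in row
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def _read_dosage_tsv(path, cohort_id: str) -> GenotypeDataset:
    with open(path) as fh:
        counted_line = fh.readline().rstrip("\n").split("\t")
        other_line = fh.readline().rstrip("\n").split("\t")
        header = fh.readline().rstrip("\n").split("\t")
        if counted_line[0] != "#counted_allele" or other_line[0] != "#other_allele":
            raise GenotypeError(f"{path}: missing allele metadata header lines")
        variant_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample_ids.append(parts[0])
            rows.append(
                np.array(
                    [np.nan if c == MISSING_SENTINEL else float(c) for c in parts[1:]]
                )
            )
    dosage = (
        np.vstack(rows) if rows else np.empty((0, len(variant_ids)))
    )
    return GenotypeDataset(
        cohort_id=cohort_id,
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        counted_allele=np.array(counted_line[1:]),
        other_allele=np.array(other_line[1:]),
        dosage=dosage,
    )


def _read_vcf(path, cohort_id: str) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    counted: list[str] = []
    other: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid in set(variant_ids):
            raise GenotypeError(f"{path}: duplicate variant ID {vid!r}")
        variant_ids.append(vid)
        counted.append(var.ALT[0] if var.ALT else ".")
        other.append(var.REF)
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, float).reshape(-1)
            col = np.where(col < -1, np.nan, col)  # cyvcf2 missing sentinel
        else:
            # GT allele count of the ALT-counted allele; missing -> NaN
            col = np.empty(len(sample_ids))
            for s, gt in enumerate(var.genotypes):
                a = gt[:-1]  # trailing element is phasing
                col[s] = np.nan if any(x < 0 for x in a) else float(
                    sum(1 for x in a if x > 0)
                )
        cols.append(col)
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    )
    return GenotypeDataset(
        cohort_id=cohort_id,
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        counted_allele=np.array(counted),
        other_allele=np.array(other),
        dosage=dosage,
    )


def read_genotypes(path, format: str = "dosage_tsv", cohort_id: str = "cohort") -> GenotypeDataset:
    """Read genotypes from ``dosage_tsv`` or ``vcf``.

    VCF uses the DS FORMAT field when present, else the GT allele count of
    the first ALT allele; ``./.`` genotypes become NaN.
    """
    if format == "dosage_tsv":
        return _read_dosage_tsv(path, cohort_id)
    if format == "vcf":
        return _read_vcf(path, cohort_id)
    raise GenotypeError(f"unknown genotype format {format!r}")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-separated phenotype/covariate/outcome table (sample ID first)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# allele harmonization


def _is_palindromic(a: str, b: str) -> bool:
    return {a, b} in PALINDROMIC_PAIRS


def harmonize(stats: SummaryStatsTable, geno: GenotypeDataset) -> pd.DataFrame:
    """Resolve allele coding between summary stats and genotypes.

    Returns a HarmonizationMap: one row per variant in the intersection with
    ``action`` in {keep, flip_weight, drop} and ``reason`` in
    {match, allele_swap, palindromic, mismatch}.  Strand-ambiguous (A/T, C/G)
    variants are always dropped; ``flip_weight`` means the scorer counts the
    complementary dosage 2-d while keeping the published weight.
    """
    geno_alleles = pd.DataFrame(
        {"counted": geno.counted_allele, "other": geno.other_allele},
        index=pd.Index(geno.variant_ids, name="variant_id"),
    )
    shared = stats.records.index.intersection(geno_alleles.index)
    st = stats.records.loc[shared]
    ga = geno_alleles.loc[shared]

    actions = np.full(len(shared), "drop", dtype=object)
    reasons = np.full(len(shared), "mismatch", dtype=object)

    pal = np.array(
        [_is_palindromic(a, b) for a, b in zip(st["effect_allele"], st["other_allele"])]
    )
    match = (st["effect_allele"].to_numpy() == ga["counted"].to_numpy()) & (
        st["other_allele"].to_numpy() == ga["other"].to_numpy()
    )
    swap = (st["effect_allele"].to_numpy() == ga["other"].to_numpy()) & (
        st["other_allele"].to_numpy() == ga["counted"].to_numpy()
    )

    actions[match & ~pal] = "keep"
    reasons[match & ~pal] = "match"
    actions[swap & ~pal] = "flip_weight"
    reasons[swap & ~pal] = "allele_swap"
    reasons[pal] = "palindromic"

    return pd.DataFrame({"action": actions, "reason": reasons}, index=shared)
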
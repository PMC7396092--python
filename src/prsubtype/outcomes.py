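"""Class-wise association of treatment outcomes and baseline features.

Pre/post treatment changes are tested with paired Student t-tests per
outcome, for all patients together and within each class.  Baseline
features are modeled with class-membership dummies (largest class as the
reference) plus sex, age and assigned-drug covariates, by ordinary least
squares or logistic regression.  Raw p-values are reported unadjusted;
Bonferroni correction appears only as significance flags with the family
size recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cluster import ClassAssignment


class OutcomeError(ValueError):
    pass


VISITS = ("baseline", "visit6", "end_phase1")


@dataclass
class PairedChangeResult:
    """Paired t-test on per-subject pre/post differences for one outcome."""

    outcome_id: str
    class_label: str  # class name or "all"
    n_pairs: int
    mean_diff: float
    std_err: float
    t: float
    df: int
    ci95: tuple[float, float]
    p_two_sided: float
    direction: str  # "pre_minus_post" | "post_minus_pre"
    degenerate: bool = False  # zero-variance differences with nonzero mean


def p_from_t(t: float, df: int) -> float:
    """Two-sided Student-t tail probability."""
    if df < 1:
        raise OutcomeError(f"df must be >= 1, got {df}")
    if math.isinf(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), df))


def paired_change_test(
    pre: np.ndarray,
    post: np.ndarray,
    direction: str = "pre_minus_post",
    outcome_id: str = "",
    class_label: str = "all",
) -> PairedChangeResult:
    """Paired Student t-test; incomplete pairs are dropped.

    ``direction`` fixes the sign convention of the reported difference:
    symptom counts are reported as pre - post (positive = reduction =
    improvement); cognitive and laboratory measures as post - pre.
    """
    if direction not in ("pre_minus_post", "post_minus_pre"):
        raise OutcomeError(f"unknown direction {direction!r}")
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise OutcomeError("pre and post must have equal length")
    ok = ~(np.isnan(pre) | np.isnan(post))
    d = pre[ok] - post[ok] if direction == "pre_minus_post" else post[ok] - pre[ok]
    n = len(d)
    if n < 2:
        raise OutcomeError(f"need >= 2 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        if mean == 0:
            return PairedChangeResult(
                outcome_id, class_label, n, 0.0, 0.0, 0.0, df, (0.0, 0.0), 1.0, direction
            )
        t = math.inf if mean > 0 else -math.inf
        return PairedChangeResult(
            outcome_id, class_label, n, mean, 0.0, t, df, (mean, mean), 0.0,
            direction, degenerate=True,
        )
    se = sd / math.sqrt(n)
    t = mean / se
    tcrit = float(stats.t.ppf(0.975, df))
    ci = (mean - tcrit * se, mean + tcrit * se)
    return PairedChangeResult(
        outcome_id, class_label, n, mean, se, t, df, ci, p_from_t(t, df), direction
    )


# ---------------------------------------------------------------------------
# baseline association models


@dataclass
class BaselineAssocResult:
    outcome_id: str
    family: str  # "linear" | "logistic"
    reference_class: str
    table: pd.DataFrame  # index class; cols coefficient, std_err, p, stable
    covariates: list[str]


def _design(classes: ClassAssignment, covariates: pd.DataFrame | None, index):
    labels = classes.labels.reindex(index)
    order = classes.class_names
    ref = order[0]
    dummies = pd.DataFrame(
        {f"class_{c}": (labels == c).astype(float) for c in order[1:]}, index=index
    )
    X = dummies
    cov_names: list[str] = []
    if covariates is not None:
        cov = covariates.reindex(index)
        cov_numeric = pd.get_dummies(cov, drop_first=True).astype(float)
        cov_names = list(cov_numeric.columns)
        X = pd.concat([dummies, cov_numeric], axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X, ref, order, cov_names


def baseline_class_model(
    outcome: pd.Series,
    classes: ClassAssignment,
    covariates: pd.DataFrame | None = None,
    family: str = "linear",
) -> BaselineAssocResult:
    """Regress a baseline feature on class dummies plus covariates.

    The largest class is the omitted reference; per-dummy Wald p-values are
    reported.  A constant outcome returns all-zero coefficients with p 1.
    A class with < 2 modeled samples is flagged unstable; exactly collinear
    covariates are fatal.
    """
    if family not in ("linear", "logistic"):
        raise OutcomeError(f"unknown family {family!r}")
    y = pd.to_numeric(outcome, errors="coerce")
    idx = y.index[y.notna()]
    y = y.loc[idx].to_numpy(float)
    if classes.labels.reindex(idx).isna().any():
        raise OutcomeError("outcome contains samples without a class label")
    X, ref, order, cov_names = _design(classes, covariates, idx)

    counts = classes.labels.reindex(idx).value_counts()
    unstable = {c: counts.get(c, 0) < 2 for c in order[1:]}

    if np.ptp(y) == 0:
        table = pd.DataFrame(
            {"coefficient": 0.0, "std_err": np.nan, "p": 1.0,
             "stable": [not unstable[c] for c in order[1:]]},
            index=pd.Index(order[1:], name="class"),
        )
        return BaselineAssocResult(outcome.name or "", family, ref, table, cov_names)

    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name the collinear columns by greedy QR-style elimination
        keep, names = [], list(X.columns)
        bad = []
        for j in range(Xv.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(Xv[:, trial]) == len(trial):
                keep = trial
            else:
                bad.append(names[j])
        raise OutcomeError(f"collinear design columns: {bad}")

    if family == "linear":
        res = sm.OLS(y, Xv).fit()
    else:
        res = sm.Logit(y, Xv).fit(disp=0, maxiter=100)
    cols = list(X.columns)
    rows = []
    for c in order[1:]:
        j = cols.index(f"class_{c}")
        rows.append(
            {
                "class": c,
                "coefficient": float(res.params[j]),
                "std_err": float(res.bse[j]),
                "p": float(res.pvalues[j]),
                "stable": not unstable[c],
            }
        )
    table = pd.DataFrame(rows).set_index("class")
    return BaselineAssocResult(outcome.name or "", family, ref, table, cov_names)


# ---------------------------------------------------------------------------
# per-class change reports


@dataclass
class OutcomeContrast:
    """Which visits to compare for one outcome, and how to report the sign."""

    outcome_id: str
    visit_pre: str
    visit_post: str
    direction: str  # pre_minus_post | post_minus_pre
    family: str  # e.g. "symptom", "cognitive", "lab"
    family_size: int  # Bonferroni family size (tests per category)


def _wide_values(outcomes: pd.DataFrame, outcome_id: str, visit: str) -> pd.Series:
    sel = outcomes[(outcomes["outcome_id"] == outcome_id) & (outcomes["visit"] == visit)]
    dup = sel["sample_id"].duplicated()
    if dup.any():
        raise OutcomeError(
            f"duplicate value for outcome {outcome_id!r} at visit {visit!r}"
        )
    return sel.set_index("sample_id")["value"]


def per_class_report(
    outcomes: pd.DataFrame,
    classes: ClassAssignment,
    contrasts: list[OutcomeContrast],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One paired test for "all" plus one per class, per outcome contrast.

    ``outcomes`` is a long table with columns sample_id, visit, outcome_id,
    value.  Raw p-values are never adjusted in place; the Bonferroni family
    size is recorded and significance flags are derived from it.
    """
    required = {"sample_id", "visit", "outcome_id", "value"}
    if not required.issubset(outcomes.columns):
        raise OutcomeError(f"outcome table must have columns {sorted(required)}")
    rows = []
    for ct in contrasts:
        pre = _wide_values(outcomes, ct.outcome_id, ct.visit_pre)
        post = _wide_values(outcomes, ct.outcome_id, ct.visit_post)
        ids = pre.index.union(post.index)
        pre_v = pre.reindex(ids).to_numpy(float)
        post_v = post.reindex(ids).to_numpy(float)
        groups = [("all", np.ones(len(ids), bool))]
        lab = classes.labels.reindex(ids)
        for c in classes.class_names:
            groups.append((c, (lab == c).to_numpy()))
        for name, mask in groups:
            res = paired_change_test(
                pre_v[mask], post_v[mask], ct.direction, ct.outcome_id, name
            )
            p = res.p_two_sided
            rows.append(
                {
                    "outcome_id": ct.outcome_id,
                    "family": ct.family,
                    "class": name,
                    "n_pairs": res.n_pairs,
                    "mean_diff": res.mean_diff,
                    "std_err": res.std_err,
                    "t": res.t,
                    "df": res.df,
                    "ci95_low": res.ci95[0],
                    "ci95_high": res.ci95[1],
                    "p": p,
                    "direction": res.direction,
                    "bonferroni_family_size": ct.family_size,
                    "significant_raw": bool(p <= alpha),
                    "significant_bonferroni": bool(p * ct.family_size <= alpha),
                }
            )
    return pd.DataFrame(rows)


def class_summary(report: pd.DataFrame, classes: ClassAssignment) -> pd.DataFrame:
    """Per-class roll-up: size plus Bonferroni-surviving improvements."""
    rows = []
    n_total = len(classes.labels)
    for c in classes.class_names:
        sub = report[(report["class"] == c) & report["significant_bonferroni"]]
        rows.append(
            {
                "class": c,
                "n": classes.size_of(c),
                "pct": 100.0 * classes.size_of(c) / n_total,
                "significant_outcomes": ";".join(sorted(sub["outcome_id"])) or "-",
            }
        )
    return pd.DataFrame(rows).set_index("class")
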
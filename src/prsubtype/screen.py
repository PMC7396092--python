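"""Cross-cohort screening of candidate comorbid traits.

Each candidate trait's polygenic score is regressed on case/control status
by logistic regression in every discovery cohort.  A trait is selected when
its Wald p-value is at or below the threshold (default 0.15) in *all*
cohorts and the coefficient has the same sign everywhere.  Non-converged
fits (e.g. quasi-complete separation) exclude the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .prs import PRSMatrix


class ScreenError(ValueError):
    pass


#: coefficient magnitude on standardized x beyond which the fit is flagged
#: as quasi-separated (log-odds slopes this large are not finite MLEs in
#: practice on standardized scores)
SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    estimate: float
    std_err: float
    z: float
    p: float
    converged: bool
    n: int


def fit_logistic(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit; Wald z and two-sided p for ``x``.

    A constant predictor carries no information and returns estimate 0,
    p 1 by convention.  Quasi-complete separation (coefficient magnitude
    > 15 on standardized x) yields a flagged non-converged result with a
    missing p-value.  A single-class outcome is fatal.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape:
        raise ScreenError("y and x must have the same length")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ScreenError("y must be binary 0/1")
    if len(classes) < 2:
        raise ScreenError("outcome has a single class; logistic fit undefined")

    sd_x = x.std(ddof=0)
    if sd_x == 0:
        return LogisticFit(0.0, np.nan, 0.0, 1.0, True, len(y))

    X = x[:, None]
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    X = sm.add_constant(X, has_constant="add")
    n_params = X.shape[1]
    if len(y) <= n_params:
        raise ScreenError("more parameters than observations")

    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton", tol=1e-8)
        est = float(res.params[1])
        se = float(res.bse[1])
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:  # PerfectSeparation / singular Hessian
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, len(y))

    if not converged or abs(est * sd_x) > SEPARATION_BOUND:
        return LogisticFit(est, se, np.nan, np.nan, False, len(y))
    z = est / se
    from scipy import stats

    p = 2.0 * stats.norm.sf(abs(z))
    return LogisticFit(est, se, z, p, True, len(y))


def screen_traits(
    fits_by_trait: dict[str, dict[str, LogisticFit]],
    p_threshold: float = 0.15,
) -> pd.DataFrame:
    """Apply the consistency rule across cohorts.

    Selected <=> p <= threshold in every cohort AND identical coefficient
    sign across cohorts AND every fit converged.  Ties at exactly the
    threshold are selected (the rule is <=).  Returns one row per trait
    with per-cohort estimate/std_err/z/p columns, a ``direction_concordant``
    flag and the ``selected`` flag.
    """
    rows = []
    for trait, per_cohort in fits_by_trait.items():
        if not per_cohort:
            raise ScreenError(f"trait {trait!r} has no cohort results")
        row: dict = {"trait_id": trait}
        converged = True
        ps, signs = [], []
        for cohort, fit in per_cohort.items():
            row[f"{cohort}_estimate"] = fit.estimate
            row[f"{cohort}_std_err"] = fit.std_err
            row[f"{cohort}_z"] = fit.z
            row[f"{cohort}_p"] = fit.p
            converged &= fit.converged
            ps.append(fit.p)
            signs.append(np.sign(fit.estimate))
        concordant = bool(converged and len(set(signs)) == 1 and signs[0] != 0)
        row["direction_concordant"] = concordant
        row["selected"] = bool(
            converged
            and concordant
            and all(np.isfinite(p) and p <= p_threshold for p in ps)
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait_id")


def selected_traits(screen_table: pd.DataFrame) -> list[str]:
    return list(screen_table.index[screen_table["selected"]])


def run_screen(
    prs_by_cohort: dict[str, PRSMatrix],
    phenotype_by_cohort: dict[str, pd.Series],
    candidate_traits: list[str],
    p_threshold: float = 0.15,
    covariates_by_cohort: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Fit every candidate trait in every cohort, then apply the rule.

    ``phenotype_by_cohort`` maps sample IDs to 'case'/'control'; samples
    with unknown phenotype are excluded from the fit for that cohort.
    """
    fits: dict[str, dict[str, LogisticFit]] = {t: {} for t in candidate_traits}
    for cohort, prs in prs_by_cohort.items():
        pheno = phenotype_by_cohort[cohort].reindex(prs.sample_ids)
        known = pheno.isin(["case", "control"]).to_numpy()
        y = (pheno[known] == "case").to_numpy(float)
        cov = None
        if covariates_by_cohort and cohort in covariates_by_cohort:
            cov = covariates_by_cohort[cohort].reindex(prs.sample_ids)[known]
        for trait in candidate_traits:
            x = prs.scores[trait].to_numpy(float)[known]
            fits[trait][cohort] = fit_logistic(y, x, cov)
    return screen_traits(fits, p_threshold=p_threshold)
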
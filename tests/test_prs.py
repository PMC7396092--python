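import numpy as np
import pandas as pd
import pytest

from conftest import make_geno, make_stats
from prsubtype.io import harmonize
from prsubtype.prs import (
    PRSError,
    PRSMatrix,
    WeightSet,
    build_weights,
    score_samples,
    select_joint_markers,
    select_single_markers,
    standardize,
)


def _keep_map(variants):
    return pd.DataFrame(
        {"action": "keep", "reason": "match"}, index=pd.Index(variants, name="variant_id")
    )


def _weights(d):
    entries = pd.DataFrame(
        {"weight": list(d.values()), "flip": False},
        index=pd.Index(list(d), name="variant_id"),
    )
    return WeightSet("t", entries)


class TestJointSelection:
    def test_hand_enumerated_example(self):
        focal = make_stats("scz", "binary",
                           {"rs1": ("A", "G", 1.1, 0.01),
                            "rs2": ("A", "G", 1.1, 0.20),
                            "rs3": ("A", "G", 1.1, 0.04)})
        trait = make_stats("t", "binary",
                           {"rs1": ("A", "G", 1.1, 0.03),
                            "rs2": ("A", "G", 1.1, 0.01),
                            "rs3": ("A", "G", 1.1, 0.06)})
        assert select_joint_markers(focal, trait, 0.05) == ["rs1"]

    def test_alpha_one_gives_full_intersection(self):
        focal = make_stats("scz", "binary", {"rs1": ("A", "G", 1.1, 0.9),
                                             "rs2": ("A", "G", 1.1, 0.5)})
        trait = make_stats("t", "binary", {"rs2": ("A", "G", 1.1, 0.99),
                                           "rs3": ("A", "G", 1.1, 0.01)})
        assert select_joint_markers(focal, trait, 1.0) == ["rs2"]

    def test_disjoint_sets_give_empty_with_warning(self):
        focal = make_stats("scz", "binary", {"rs1": ("A", "G", 1.1, 0.01)})
        trait = make_stats("t", "binary", {"rs9": ("A", "G", 1.1, 0.01)})
        with pytest.warns(UserWarning, match="no jointly significant"):
            assert select_joint_markers(focal, trait) == []

    def test_lowering_alpha_never_enlarges_selection(self, rng):
        rows_f = {f"rs{i}": ("A", "G", 1.1, rng.uniform()) for i in range(50)}
        rows_t = {f"rs{i}": ("A", "G", 1.1, rng.uniform()) for i in range(50)}
        focal, trait = make_stats("scz", "binary", rows_f), make_stats("t", "binary", rows_t)
        prev = None
        import warnings
        for alpha in (1.0, 0.5, 0.2, 0.1, 0.05, 0.01, 0.001):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cur = set(select_joint_markers(focal, trait, alpha))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_single_trait_rule_for_focal_score(self):
        focal = make_stats("scz", "binary", {"rs1": ("A", "G", 1.1, 0.04),
                                             "rs2": ("A", "G", 1.1, 0.06)})
        assert select_single_markers(focal, 0.05) == ["rs1"]


class TestWeights:
    def test_log_or_weighting(self):
        stats = make_stats("t", "binary", {"rs1": ("A", "G", 1.0, 0.01),
                                           "rs2": ("A", "G", 2.0, 0.01)})
        ws = build_weights(stats, ["rs1", "rs2"], _keep_map(["rs1", "rs2"]))
        assert ws.entries.loc["rs1", "weight"] == 0.0
        assert np.isclose(ws.entries.loc["rs2", "weight"], np.log(2.0))

    def test_quantitative_beta_passes_through(self):
        stats = make_stats("t", "quantitative", {"rs1": ("A", "G", -0.12, 0.01)})
        ws = build_weights(stats, ["rs1"], _keep_map(["rs1"]))
        assert ws.entries.loc["rs1", "weight"] == -0.12

    def test_drop_actions_excluded(self):
        stats = make_stats("t", "binary", {"rs1": ("A", "T", 1.5, 0.01),
                                           "rs2": ("A", "G", 1.5, 0.01)})
        geno = make_geno([[1, 1]], counted=["A", "A"], other=["T", "G"])
        ws = build_weights(stats, ["rs1", "rs2"], harmonize(stats, geno))
        assert list(ws.entries.index) == ["rs2"]  # palindromic rs1 dropped


class TestScoring:
    def test_hand_computed_sum(self):
        geno = make_geno([[2, 1]])
        ws = _weights({"rs1": 0.2, "rs2": -0.5})
        assert np.isclose(score_samples(geno, ws)[0], -0.1)

    def test_zero_weights_zero_scores(self):
        geno = make_geno([[2, 1], [0, 1]])
        ws = _weights({"rs1": 0.0, "rs2": 0.0})
        assert np.allclose(score_samples(geno, ws), 0.0)

    def test_zero_marker_set_warns_and_returns_zeros(self):
        geno = make_geno([[2, 1]])
        ws = WeightSet("t", pd.DataFrame(columns=["weight", "flip"]))
        with pytest.warns(UserWarning, match="zero-marker"):
            assert np.allclose(score_samples(geno, ws), 0.0)

    def test_mean_impute_uses_cohort_mean(self):
        # rs1 missing for sample 1; cohort mean over observed is (0+2)/2 = 1.0
        geno = make_geno([[np.nan, 1], [0, 1], [2, 1]])
        ws = _weights({"rs1": 0.2, "rs2": -0.5})
        s = score_samples(geno, ws, "mean_impute")
        assert np.isclose(s[0], 0.2 * 1.0 + 1 * -0.5)

    def test_omit_rescale_scales_by_marker_count(self):
        geno = make_geno([[np.nan, 1]])
        ws = _weights({"rs1": 0.2, "rs2": -0.5})
        s = score_samples(geno, ws, "omit_rescale")
        assert np.isclose(s[0], (-0.5) * 2 / 1)

    def test_matches_naive_double_loop(self, rng):
        n, m = 20, 50
        dosage = rng.uniform(0, 2, size=(n, m))
        dosage[rng.random((n, m)) < 0.05] = np.nan
        geno = make_geno(dosage)
        w = rng.normal(size=m)
        flip = rng.random(m) < 0.3
        entries = pd.DataFrame({"weight": w, "flip": flip},
                               index=pd.Index(geno.variant_ids, name="variant_id"))
        ws = WeightSet("t", entries)
        fast = score_samples(geno, ws, "mean_impute")
        # naive: flip dosages, column means, double loop
        D = dosage.copy()
        for j in range(m):
            if flip[j]:
                D[:, j] = 2 - D[:, j]
        col_mean = np.array([np.nanmean(D[:, j]) for j in range(m)])
        slow = np.zeros(n)
        for i in range(n):
            for j in range(m):
                d = D[i, j]
                if np.isnan(d):
                    d = col_mean[j]
                slow[i] += w[j] * d
        assert np.allclose(fast, slow, atol=1e-10, rtol=0)

    def test_linearity_over_disjoint_weight_sets(self, rng):
        geno = make_geno(rng.uniform(0, 2, size=(10, 8)))
        ids = geno.variant_ids
        w1 = _weights({v: rng.normal() for v in ids[:4]})
        w2 = _weights({v: rng.normal() for v in ids[4:]})
        union = WeightSet("t", pd.concat([w1.entries, w2.entries]))
        assert np.allclose(
            score_samples(geno, union),
            score_samples(geno, w1) + score_samples(geno, w2),
            atol=1e-12,
        )

    def test_flip_algebraic_identity(self, rng):
        w = rng.normal(size=10)
        d = rng.uniform(0, 2, size=10)
        assert np.allclose(w * d, (-w) * (2 - d) + 2 * w, atol=1e-12)

    def test_flip_consistency_after_standardization(self, rng):
        """Scoring swapped-allele stats on flipped dosages equals scoring the
        correctly oriented data, up to the constant absorbed by z-scoring."""
        n, m = 30, 12
        dosage = rng.uniform(0, 2, size=(n, m)).round(3)
        geno = make_geno(dosage, counted=["A"] * m, other=["G"] * m)
        beta = rng.normal(size=m).round(3)
        p = {v: 0.01 for v in geno.variant_ids}
        direct = make_stats(
            "t", "quantitative",
            {v: ("A", "G", beta[j], p[v]) for j, v in enumerate(geno.variant_ids)},
        )
        swapped = make_stats(
            "t", "quantitative",
            {v: ("G", "A", -beta[j], p[v]) for j, v in enumerate(geno.variant_ids)},
        )
        s_direct = score_samples(geno, build_weights(direct, geno.variant_ids,
                                                     harmonize(direct, geno)))
        s_swap = score_samples(geno, build_weights(swapped, geno.variant_ids,
                                                   harmonize(swapped, geno)))

        def z(x):
            return (x - x.mean()) / x.std(ddof=1)

        assert np.allclose(z(s_direct), z(s_swap), atol=1e-9)


class TestStandardize:
    def test_hand_z_scores(self):
        prs = PRSMatrix("c", pd.DataFrame({"t": [1.0, 2.0, 3.0]}))
        z = standardize(prs)
        assert np.allclose(z.scores["t"], [-1, 0, 1])
        assert z.standardized

    def test_idempotent(self, rng):
        prs = PRSMatrix("c", pd.DataFrame(rng.normal(size=(20, 3)),
                                          columns=list("abc")))
        once = standardize(prs)
        twice = standardize(once)
        assert np.allclose(once.scores, twice.scores, atol=1e-12)
        assert np.allclose(once.scores.mean(), 0, atol=1e-8)
        assert np.allclose(once.scores.std(ddof=1), 1, atol=1e-8)

    def test_constant_column_is_fatal_and_named(self):
        prs = PRSMatrix("c", pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))
        with pytest.raises(PRSError, match="flat"):
            standardize(prs)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    ps=st.lists(
        st.tuples(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0)),
        min_size=1, max_size=40,
    ),
    alpha=st.floats(0.001, 1.0),
)
def test_joint_selection_definition_property(ps, alpha):
    """The selected set is exactly {v: p_focal <= alpha and p_trait <= alpha}."""
    import warnings
    rows_f = {f"rs{i}": ("A", "G", 1.1, pf) for i, (pf, _) in enumerate(ps)}
    rows_t = {f"rs{i}": ("A", "G", 1.1, pt) for i, (_, pt) in enumerate(ps)}
    focal = make_stats("scz", "binary", rows_f)
    trait = make_stats("t", "binary", rows_t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        got = set(select_joint_markers(focal, trait, alpha))
    want = {f"rs{i}" for i, (pf, pt) in enumerate(ps) if pf <= alpha and pt <= alpha}
    assert got == want
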
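import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from senescreen import simulate
from senescreen.heritability import BASE, SldscRegression, compute_ld_scores, fit_sldsc
from senescreen.meta import (
    MetaResult,
    cluster_group_association,
    compare_gene_sets,
    compare_gene_sets_paired,
    one_sided_test,
    per_snp_difference,
    random_effects_meta,
    select_and_cluster_traits,
)
from senescreen.pipeline import tau_for_enrichment


def _handmade_fit(tau, annot: pd.DataFrame, n_blocks=4):
    """An SldscRegression whose coefficients are set by hand (no noise)."""
    est = SldscRegression(n_blocks=n_blocks)
    A = annot.to_numpy(dtype=float)
    est.snp_count_ = len(annot)
    est.annotation_names_ = list(annot.columns)
    est.annot_sizes_ = pd.Series(A.sum(axis=0), index=annot.columns)
    est.tau_ = pd.Series(np.asarray(tau, float), index=annot.columns)
    est.tau_blocks_ = np.tile(np.asarray(tau, float), (n_blocks, 1))
    est._finalize(A)
    return est


class TestPerSnpDifference:
    def test_unit_enrichment_gives_zero_difference(self):
        annot = pd.DataFrame({BASE: np.ones(8, int),
                              "s": [1, 1, 0, 0, 0, 0, 0, 0]})
        fit = _handmade_fit([0.125, 0.0], annot)  # uniform per-SNP h2
        assert fit.enrichment_["s"] == pytest.approx(1.0)
        d, se = per_snp_difference(fit, "s")
        assert d == pytest.approx(0.0, abs=1e-15)

    def test_arithmetic_matches_printed_formula(self):
        # h2_a = 0.5, h2 = 1, |a| = p/4 = 2 -> d = (4/3)/p
        annot = pd.DataFrame({BASE: np.ones(8, int),
                              "s": [1, 1, 0, 0, 0, 0, 0, 0]})
        sigma_out = 0.5 / 6
        fit = _handmade_fit([sigma_out, 0.25 - sigma_out], annot)
        assert fit.h2_total_ == pytest.approx(1.0)
        assert fit.h2_annot_["s"] == pytest.approx(0.5)
        d, _ = per_snp_difference(fit, "s")
        assert d == pytest.approx((4 / 3) / 8)

    def test_degenerate_annotation_rejected(self):
        annot = pd.DataFrame({BASE: np.ones(4, int), "s": [0, 0, 0, 0]})
        fit = _handmade_fit([0.1, 0.0], annot)
        with pytest.raises(ValueError, match="undefined"):
            per_snp_difference(fit, "s")
        with pytest.raises(ValueError, match="undefined"):
            per_snp_difference(fit, BASE)

    def test_jackknife_se_matches_direct_delete_block_recomputation(self):
        _, snp_map = simulate.simulate_genome(2, 400, 8, 10_000_000, seed=0)
        rng = np.random.default_rng(1)
        a = np.zeros(400, int)
        a[rng.choice(400, 40, replace=False)] = 1
        annot = pd.DataFrame({BASE: np.ones(400, int), "s": a})
        ld = compute_ld_scores(snp_map, annot, rho=0.3)
        ss, _ = simulate.simulate_gwas(snp_map, annot,
                                       tau_for_enrichment(a, 0.3, 2.0),
                                       20_000, rho=0.3, seed=2)
        fit = fit_sldsc(ss, ld, annot, n_blocks=4, two_pass_weights=False,
                        chisq_cap=None)
        d, se = per_snp_difference(fit, "s")

        # independent delete-one-block WLS recomputation
        A = annot.to_numpy(float)
        X = np.column_stack([20_000 * ld.to_numpy(), np.ones(400)])
        y = ss["Z"].to_numpy() ** 2
        w = np.sqrt(1.0 / np.maximum(ld[BASE].to_numpy(), 1.0))
        blocks = np.array_split(np.arange(400), 4)
        d_del = []
        for idx in blocks:
            keep = np.ones(400, bool)
            keep[idx] = False
            coef = np.linalg.lstsq((X * w[:, None])[keep], (y * w)[keep],
                                   rcond=None)[0]
            persnp = A @ coef[:2]
            h2, h2a = persnp.sum(), persnp[a == 1].sum()
            d_del.append(h2a / 40 - (h2 - h2a) / 360)
        d_del = np.array(d_del)
        se_oracle = np.sqrt(3 / 4 * ((d_del - d_del.mean()) ** 2).sum())
        assert se == pytest.approx(se_oracle, rel=1e-10)


class TestRandomEffectsMeta:
    def test_identical_studies_pool_exactly(self):
        m = random_effects_meta([0.8, 0.8, 0.8], [0.1, 0.1, 0.1])
        assert m.pooled == pytest.approx(0.8)
        assert m.tau2 == 0.0

    def test_two_study_dersimonian_laird_closed_form(self):
        est, se = np.array([1.0, 2.0]), np.array([0.1, 0.1])
        m = random_effects_meta(est, se)
        # hand computation of the DL estimator
        w = 1 / se**2
        fixed = (w * est).sum() / w.sum()
        q = (w * (est - fixed) ** 2).sum()
        tau2 = max(0.0, (q - 1) / (w.sum() - (w**2).sum() / w.sum()))
        ws = 1 / (se**2 + tau2)
        assert m.tau2 == pytest.approx(tau2, abs=1e-10)
        assert m.pooled == pytest.approx((ws * est).sum() / ws.sum(),
                                         abs=1e-10)
        assert m.se == pytest.approx(1 / np.sqrt(ws.sum()), abs=1e-10)

    def test_single_study_returned_unchanged(self):
        m = random_effects_meta([1.3], [0.2])
        assert (m.pooled, m.se, m.tau2) == (1.3, 0.2, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            random_effects_meta([], [])
        with pytest.raises(ValueError):
            random_effects_meta([1.0], [0.0])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.01, 2)),
                    min_size=1, max_size=8))
    def test_pooled_within_study_range(self, studies):
        est = [e for e, _ in studies]
        se = [s for _, s in studies]
        m = random_effects_meta(est, se)
        assert min(est) - 1e-9 <= m.pooled <= max(est) + 1e-9
        assert m.tau2 >= 0

    def test_zero_heterogeneity_equals_fixed_effects(self):
        est, se = [1.0, 1.1, 0.9], [0.5, 0.5, 0.5]
        m = random_effects_meta(est, se)
        w = 1 / np.array(se) ** 2
        assert m.tau2 == 0.0
        assert m.pooled == pytest.approx((w * est).sum() / w.sum())


class TestOneSidedTest:
    def test_reference_points(self):
        assert one_sided_test(MetaResult(0.0, 1.0, 0.0, 1)) == 0.5
        assert one_sided_test(
            MetaResult(1.645, 1.0, 0.0, 1)) == pytest.approx(0.05, abs=2e-3)

    def test_matches_normal_cdf_oracle(self):
        rng = np.random.default_rng(3)
        for z in rng.normal(0, 2, 10):
            p = one_sided_test(MetaResult(z, 1.0, 0.0, 1))
            assert p == pytest.approx(1 - stats.norm.cdf(z), abs=1e-12)


class TestCompareGeneSets:
    def test_identical_metas_give_half(self):
        m = MetaResult(1.0, 0.2, 0.0, 5)
        assert compare_gene_sets(m, m) == pytest.approx(0.5)

    def test_dominant_set_drives_p_to_zero(self):
        a = MetaResult(5.0, 0.01, 0.0, 5)
        b = MetaResult(1.0, 0.01, 0.0, 5)
        assert compare_gene_sets(a, b) < 1e-10

    def test_matches_hand_z_computation(self):
        a, b = MetaResult(1.5, 0.3, 0.0, 4), MetaResult(1.0, 0.4, 0.0, 4)
        z = (1.5 - 1.0) / np.sqrt(0.3**2 + 0.4**2)
        assert compare_gene_sets(a, b) == pytest.approx(stats.norm.sf(z))

    def test_paired_comparison(self):
        est_a, se_a = [2.0, 2.1, 1.9], [0.1, 0.1, 0.1]
        est_b, se_b = [1.0, 1.0, 1.0], [0.1, 0.1, 0.1]
        assert compare_gene_sets_paired(est_a, se_a, est_b, se_b) < 1e-6


class TestSelectAndClusterTraits:
    def _matrices(self):
        enr = pd.DataFrame(
            {"setA": [3.0, 2.8, 1.0, 0.9], "setB": [1.0, 1.1, 2.9, 3.1]},
            index=["t1", "t2", "t3", "t4"])
        pv = pd.DataFrame({"setA": [0.001, 0.002, 0.9, 0.8],
                           "setB": [0.9, 0.8, 0.001, 0.004]},
                          index=enr.index)
        return enr, pv

    def test_two_group_fixture_recovered(self):
        enr, pv = self._matrices()
        out = select_and_cluster_traits(enr, pv, n_clusters=2)
        assert len(out) == 4
        g1 = set(out.loc[out["cluster"] == out.loc[
            out["trait"] == "t1", "cluster"].iloc[0], "trait"])
        assert g1 == {"t1", "t2"}
        assert (out.set_index("trait")["specific_set"] ==
                pd.Series({"t1": "setA", "t2": "setA", "t3": "setB",
                           "t4": "setB"})).all()

    def test_single_passing_trait(self):
        enr, pv = self._matrices()
        pv.iloc[1:] = 1.0
        out = select_and_cluster_traits(enr, pv)
        assert list(out["trait"]) == ["t1"]
        assert out["specific_set"].iloc[0] == "setA"

    def test_none_passing_warns_and_returns_empty(self):
        enr, pv = self._matrices()
        pv[:] = 1.0
        with pytest.warns(UserWarning):
            out = select_and_cluster_traits(enr, pv)
        assert out.empty


def brute_force_fisher_two_sided(table):
    """Exhaustive enumeration of 2x2 tables at fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestClusterGroupAssociation:
    def test_concordant_table_matches_enumeration(self):
        labels = pd.Series(["inflammaging"] * 10 + ["other"] * 10,
                           index=[f"t{i}" for i in range(20)])
        aging = pd.Series([True] * 10 + [False] * 10, index=labels.index)
        table, odds, p = cluster_group_association(labels, aging)
        assert table.tolist() == [[10, 0], [0, 10]]
        assert p == pytest.approx(brute_force_fisher_two_sided(table),
                                  abs=1e-12)

    def test_independent_margins_give_p_one(self):
        labels = pd.Series(["inflammaging", "inflammaging", "other", "other"],
                           index=list("abcd"))
        aging = pd.Series([True, False, True, False], index=list("abcd"))
        _, _, p = cluster_group_association(labels, aging)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_row_swap(self):
        rng = np.random.default_rng(4)
        labels = pd.Series(rng.choice(["inflammaging", "other"], 30),
                           index=[f"t{i}" for i in range(30)])
        aging = pd.Series(rng.choice([True, False], 30), index=labels.index)
        _, _, p1 = cluster_group_association(labels, aging)
        flipped = labels.map({"inflammaging": "other",
                              "other": "inflammaging"})
        _, _, p2 = cluster_group_association(flipped, aging, focus="other")
        assert p1 == pytest.approx(p2)

    def test_degenerate_margin_warns(self):
        labels = pd.Series(["inflammaging"] * 4, index=list("abcd"))
        aging = pd.Series([True, False, True, False], index=list("abcd"))
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, p = cluster_group_association(labels, aging)
        assert p == 1.0
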
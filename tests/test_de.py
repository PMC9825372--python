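import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from primeseq import de
from primeseq.io import CountMatrix, SampleDesign


def _two_group_matrix(Y, n_test, n_ref, test_group="ELE_3min"):
    ex, lr = test_group.split("_")
    samples = [
        SampleDesign(sample_id=f"t{j}", exercise=ex, learning=lr) for j in range(n_test)
    ] + [SampleDesign(sample_id=f"r{j}") for j in range(n_ref)]
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(Y.shape[0])], samples=samples, counts=Y
    )


def _nb(rng, mean, alpha, size):
    return rng.poisson(rng.gamma(1.0 / alpha, mean * alpha, size=size))


class TestSizeFactors:
    def test_identical_samples_unity(self):
        Y = np.tile([[10], [20], [5]], (1, 4))
        cm = _two_group_matrix(Y, 2, 2)
        assert np.allclose(de.median_ratio_size_factors(cm), 1.0)

    def test_doubling_a_sample_doubles_its_factor(self, rng):
        Y = rng.poisson(50, size=(100, 4)) + 1
        s0 = de.median_ratio_size_factors(Y)
        Y2 = Y.copy()
        Y2[:, 2] *= 2
        s1 = de.median_ratio_size_factors(Y2)
        # geometric-mean reference moves by 2^(1/4) for every gene, so all
        # ratios shift by the same constant; compare relative factors
        assert np.allclose(s1[2] / s1[0], 2 * s0[2] / s0[0], rtol=1e-9)
        assert np.allclose(s1[1] / s1[0], s0[1] / s0[0], rtol=1e-9)

    def test_three_gene_toy_matches_hand_computation(self):
        Y = np.array([[2, 8], [3, 12], [5, 45]])
        # brute-force oracle: per-gene geometric mean, per-sample median ratio
        ref = np.exp(np.log(Y).mean(axis=1))
        expected = np.median(Y / ref[:, None], axis=0)
        got = de.median_ratio_size_factors(Y)
        assert np.allclose(got, expected)

    def test_no_all_positive_gene_advises_fallback(self):
        Y = np.array([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            de.median_ratio_size_factors(Y)
        sf = de.median_ratio_size_factors(Y, pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersions:
    def test_poisson_genes_negligible_dispersion(self, rng):
        # method-of-moments (var - mean)/mean^2 is symmetric around zero for
        # Poisson data, so half the genes land exactly on the floor and the
        # rest stay negligibly small relative to real overdispersion scales
        Y = rng.poisson(100, size=(500, 100))
        groups = np.zeros(100)
        alpha = de.estimate_dispersions(Y, groups, np.ones(100))
        assert (alpha == de.ALPHA_FLOOR).mean() >= 0.4
        assert (alpha < 0.005).mean() >= 0.95

    def test_recovers_planted_dispersion(self, rng):
        mu = 200.0
        Y = _nb(rng, mu, 0.5, size=(2000, 50))
        alpha = de.estimate_dispersions(Y, np.zeros(50), np.ones(50))
        assert 0.35 <= np.median(alpha) <= 0.65

    def test_constant_gene_at_floor(self):
        Y = np.full((1, 6), 7)
        alpha = de.estimate_dispersions(Y, np.zeros(6), np.ones(6))
        assert alpha[0] == de.ALPHA_FLOOR


class TestWald:
    def test_type_one_error_in_band(self):
        rng = np.random.default_rng(42)
        G, n = 2000, 50
        mu = np.exp(rng.normal(np.log(100), 1, G))
        Y = _nb(rng, mu[:, None], 0.05, size=(G, 2 * n))
        res = de.nb_wald_test(_two_group_matrix(Y, n, n), "group:ELE_3min:SED_none")
        p = res.table["p"].dropna()
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_unbiased_lfc_estimate(self):
        rng = np.random.default_rng(7)
        G, n = 1000, 10
        mu = np.exp(rng.normal(np.log(200), 0.5, G))
        Y = np.hstack(
            [
                _nb(rng, 2.0 * mu[:, None], 0.1, size=(G, n)),
                _nb(rng, mu[:, None], 0.1, size=(G, n)),
            ]
        )
        # unit size factors: the example isolates GLM bias from normalization
        # (median-of-ratios would absorb a fold change planted in every gene)
        res = de.nb_wald_test(
            _two_group_matrix(Y, n, n), "group:ELE_3min:SED_none",
            size_factors=np.ones(2 * n),
        )
        assert 0.9 <= res.table["log2fc"].mean() <= 1.1

    def test_all_zero_gene_excluded(self):
        Y = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        res = de.nb_wald_test(_two_group_matrix(Y, 2, 2), "group:ELE_3min:SED_none")
        assert np.isnan(res.table.loc["g0", "p"])
        assert np.isnan(res.table.loc["g0", "padj"])
        assert np.isfinite(res.table.loc["g1", "p"])

    def test_size_factor_equivariance(self):
        # exact equivariance: scaling every sample's counts by c is fully
        # absorbed by the size factors (intercept shift), leaving log2fc
        # untouched.  Scaling a single sample changes that sample's weight
        # in the score equation, so per-gene estimates move by O(1/n) but
        # stay close (the estimator remains consistent).
        rng = np.random.default_rng(3)
        Y = rng.poisson(100, size=(200, 8))
        cm = _two_group_matrix(Y, 4, 4)
        groups = np.array([s.group for s in cm.samples])
        disp = de.estimate_dispersions(Y, groups, de.median_ratio_size_factors(Y))
        res0 = de.nb_wald_test(cm, "group:ELE_3min:SED_none", dispersions=disp)
        # the NB dispersion is in count units: mean 3*mu at dispersion
        # alpha/3 gives IRLS weights proportional to the original fit, so
        # the rescaled problem has the identical solution
        res_all = de.nb_wald_test(
            _two_group_matrix(Y * 3, 4, 4), "group:ELE_3min:SED_none",
            dispersions=disp / 3,
        )
        lfc0 = res0.table["log2fc"].to_numpy()
        assert np.nanmax(np.abs(lfc0 - res_all.table["log2fc"].to_numpy())) < 1e-6

        Y2 = Y.copy()
        Y2[:, 0] *= 3
        res1 = de.nb_wald_test(
            _two_group_matrix(Y2, 4, 4), "group:ELE_3min:SED_none",
            dispersions=disp,
        )
        delta = np.abs(lfc0 - res1.table["log2fc"].to_numpy())
        assert np.nanmax(delta) < 0.2 and np.nanmedian(delta) < 0.05


def _factorial_matrix(Y, n_per_cell):
    samples = []
    j = 0
    for h in ("L", "R"):
        for ex in ("SED", "ELE"):
            for _ in range(n_per_cell):
                samples.append(
                    SampleDesign(
                        sample_id=f"s{j}", exercise=ex, hemisphere=h,
                        isolation="separate",
                    )
                )
                j += 1
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(Y.shape[0])], samples=samples, counts=Y
    )


class TestLRT:
    def test_full_equals_reduced_gives_null_result(self, rng):
        Y = rng.poisson(50, size=(50, 12))
        cm = _factorial_matrix(Y, 3)
        res = de.nb_lrt(cm, ["hemisphere", "exercise"], ["hemisphere", "exercise"])
        ok = res.table["p"].dropna()
        assert (ok == 1.0).all()
        assert (res.table["stat"].dropna() == 0.0).all()

    def test_non_nested_rejected(self, rng):
        Y = rng.poisson(50, size=(10, 12))
        cm = _factorial_matrix(Y, 3)
        with pytest.raises(ValueError, match="subset"):
            de.nb_lrt(cm, ["hemisphere"], ["exercise"])

    def test_planted_exercise_effect_attributed_to_exercise(self):
        rng = np.random.default_rng(12)
        G, npc = 600, 6
        mu = np.exp(rng.normal(np.log(150), 0.7, G))
        effect = np.zeros(G)
        effect[:120] = rng.uniform(0.8, 1.5, 120)  # exercise-only effect
        blocks = []
        for h in ("L", "R"):
            for ex in ("SED", "ELE"):
                m = mu[:, None] * np.exp2(effect[:, None] * (ex == "ELE"))
                blocks.append(_nb(rng, m * np.ones((G, npc)), 0.02, (G, npc)))
        Y = np.hstack(blocks)
        cm = _factorial_matrix(Y, npc)
        results = de.lrt_term_attribution(cm)
        n_ex = (results["exercise"].table["p"] < 0.05).sum()
        n_hem = (results["hemisphere"].table["p"] < 0.05).sum()
        n_int = (results["interaction"].table["p"] < 0.05).sum()
        assert n_ex > n_hem and n_ex > n_int


class TestAnova:
    def test_constant_response_is_nan(self):
        Y = np.full((1, 8), 32)
        cm = _factorial_matrix(Y, 2)
        table = de.per_gene_two_way_anova(cm, size_factors=np.ones(8))
        assert np.isnan(table.loc["g0", "p_exercise"])

    def test_balanced_toy_matches_textbook_formulas(self):
        # 2x2 with n=2 per cell; compare sequential F against the closed-form
        # balanced-design decomposition on the transformed responses
        Y = np.array([[12, 14, 20, 22, 30, 34, 44, 40]])
        cm = _factorial_matrix(Y, 2)
        sf = np.ones(8)
        table = de.per_gene_two_way_anova(cm, factors=("hemisphere", "exercise"),
                                          size_factors=sf)
        y = np.log2(Y[0] / sf + 1.0)
        cells = {
            ("L", "SED"): y[0:2], ("L", "ELE"): y[2:4],
            ("R", "SED"): y[4:6], ("R", "ELE"): y[6:8],
        }
        grand = y.mean()
        n = 2
        mean_h = {h: np.mean([cells[(h, e)] for e in ("SED", "ELE")]) for h in ("L", "R")}
        mean_e = {e: np.mean([cells[(h, e)] for h in ("L", "R")]) for e in ("SED", "ELE")}
        ss_a = 2 * n * sum((mean_h[h] - grand) ** 2 for h in ("L", "R"))
        ss_b = 2 * n * sum((mean_e[e] - grand) ** 2 for e in ("SED", "ELE"))
        ss_ab = n * sum(
            (cells[(h, e)].mean() - mean_h[h] - mean_e[e] + grand) ** 2
            for h in ("L", "R") for e in ("SED", "ELE")
        )
        ss_err = sum(((cells[k] - cells[k].mean()) ** 2).sum() for k in cells)
        mse = ss_err / 4
        assert np.isclose(table.loc["g0", "F_hemisphere"], ss_a / mse)
        assert np.isclose(table.loc["g0", "F_exercise"], ss_b / mse)
        assert np.isclose(table.loc["g0", "F_interaction"], ss_ab / mse)

    def test_planted_exercise_effect_dominates(self):
        rng = np.random.default_rng(8)
        G, npc = 400, 4
        mu = np.exp(rng.normal(np.log(150), 0.5, G))
        effect = np.zeros(G)
        effect[:100] = 1.0
        blocks = []
        for h in ("L", "R"):
            for ex in ("SED", "ELE"):
                m = mu[:, None] * np.exp2(effect[:, None] * (ex == "ELE"))
                blocks.append(_nb(rng, m * np.ones((G, npc)), 0.02, (G, npc)))
        Y = np.hstack(blocks)
        cm = _factorial_matrix(Y, npc)
        table = de.per_gene_two_way_anova(cm)
        assert (table["p_exercise"] < 0.05).sum() > (table["p_hemisphere"] < 0.05).sum()

    def test_missing_cell_rejected(self):
        samples = [
            SampleDesign(sample_id=f"s{j}", exercise="SED", hemisphere="L",
                         isolation="separate")
            for j in range(4)
        ] + [
            SampleDesign(sample_id=f"t{j}", exercise="ELE", hemisphere="R",
                         isolation="separate")
            for j in range(4)
        ]
        cm = CountMatrix(gene_ids=["g0"], samples=samples,
                         counts=np.full((1, 8), 5))
        with pytest.raises(ValueError, match="combination"):
            de.per_gene_two_way_anova(cm, size_factors=np.ones(8))


class TestBH:
    def test_single_p(self):
        assert de.adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # step-up: padj_i = min over j>=i of p_(j) * m / j
        got = de.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (de.adjust_bh([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_handling_does_not_deflate(self):
        got = de.adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(got[1])
        assert np.allclose(got[[0, 2]], de.adjust_bh([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_monotone_in_p_rank_and_bounded(self, ps):
        padj = de.adjust_bh(np.array(ps))
        assert (padj <= 1.0 + 1e-12).all()
        assert (padj >= np.array(ps) - 1e-12).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(padj[order]) >= -1e-12).all()


class TestCallDegs:
    def _result(self, rows):
        table = pd.DataFrame(rows, columns=["log2fc", "p"])
        table.index = [f"g{i}" for i in range(len(rows))]
        table["padj"] = de.adjust_bh(table["p"].to_numpy())
        table["base_mean"] = 10.0
        table["se"] = 0.1
        table["stat"] = 0.0
        return de.DEResult(table=table, test="wald", contrast="x")

    def test_default_cut_is_log2_of_1_3(self):
        assert round(de.DEFAULT_LFC_CUT, 4) == 0.3785

    def test_boundary_is_strict(self):
        res = self._result([(0.3785, 0.001)])
        degs = de.call_degs(res)
        assert degs.up == set() and degs.down == set()

    def test_down_call(self):
        res = self._result([(-0.5, 0.04)])
        assert de.call_degs(res).down == {"g0"}

    def test_misquoted_cut_warns(self):
        res = self._result([(0.5, 0.01)])
        with pytest.warns(UserWarning, match="0.3785"):
            de.call_degs(res, lfc_cut=0.3875)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-3, max_value=3),
                st.floats(min_value=0, max_value=1),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_up_down_always_disjoint_and_thresholds_respected(self, rows):
        degs = de.call_degs(self._result(rows))
        assert not (degs.up & degs.down)
        t = {f"g{i}": r for i, r in enumerate(rows)}
        for g in degs.up:
            assert t[g][0] > de.DEFAULT_LFC_CUT and t[g][1] < 0.05
        for g in degs.down:
            assert t[g][0] < -de.DEFAULT_LFC_CUT and t[g][1] < 0.05
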
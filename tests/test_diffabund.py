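"""NB Wald test, size factors, impulse model, GSEA running sum, PCA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from xenoplasma import diffabund


def nb_draw(rng, mu, phi, size=None):
    return rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * np.asarray(mu)), size=size)


class TestSizeFactors:
    def test_identical_columns_are_one(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        np.testing.assert_allclose(diffabund.size_factors(counts), 1.0)

    def test_doubling_one_column_doubles_its_factor(self):
        counts = pd.DataFrame({"a": [4, 1, 9], "b": [8, 2, 18]})
        sf = diffabund.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_hand_median_of_ratios(self):
        counts = pd.DataFrame({"a": [4, 1, 9], "b": [16, 4, 9]})
        # geometric means: 8, 2, 9 → ratios a: (.5,.5,1) b: (2,2,1); medians .5, 2
        sf = diffabund.size_factors(counts)
        np.testing.assert_allclose(sf, [0.5, 2.0])

    def test_matches_pydeseq2(self):
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            nb_draw(rng, rng.lognormal(3, 1, (60, 1)) * np.ones((60, 6)), 0.2),
            columns=[f"s{i}" for i in range(6)],
        )
        _, sf_ref = deseq2_norm(counts.T)  # pydeseq2 takes samples × genes
        ours = diffabund.size_factors(counts)
        np.testing.assert_allclose(ours.to_numpy(), np.asarray(sf_ref).ravel(), rtol=1e-8)

    def test_no_reference_gene_without_fallback(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [5, 0]})
        with pytest.raises(ValueError):
            diffabund.size_factors(counts, allow_fallback=False)
        assert (diffabund.size_factors(counts) > 0).all()


class TestNbWald:
    def test_identical_groups_null_gene(self):
        counts = pd.DataFrame(
            {f"s{i}": [50, 20] for i in range(8)}, index=["g1", "g2"]
        )
        res = diffabund.nb_wald_test(
            counts, ["A"] * 4 + ["B"] * 4, dispersion=pd.Series(0.3, index=counts.index)
        )
        assert abs(res.loc["g1", "log2FC"]) < 1e-6
        assert res.loc["g1", "pvalue"] > 0.99

    def test_needs_two_groups_of_two(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["g"])
        with pytest.raises(ValueError):
            diffabund.nb_wald_test(counts, ["A", "A", "B"])

    def test_size_factor_rescaling_near_invariance(self):
        # scaling one sample's counts and its size factor together is absorbed
        # by the offset; the NB likelihood is not exactly scale-equivariant,
        # so agreement is to tolerance, not machine precision
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            nb_draw(rng, np.tile(rng.lognormal(5, 0.5, (100, 1)), (1, 8)), 0.3),
            columns=[f"s{i}" for i in range(8)],
        )
        labels = ["A"] * 4 + ["B"] * 4
        disp = pd.Series(0.3, index=counts.index)
        sf = diffabund.size_factors(counts)
        res1 = diffabund.nb_wald_test(counts, labels, sf=sf, dispersion=disp)
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 2
        sf2 = sf.copy()
        sf2["s0"] = sf2["s0"] * 2
        res2 = diffabund.nb_wald_test(scaled, labels, sf=sf2, dispersion=disp)
        diff = (res1.log2FC - res2.log2FC).abs()
        assert diff.median() < 0.02 and diff.max() < 0.2
        assert np.corrcoef(res1.stat, res2.stat)[0, 1] > 0.99

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(11)
        G, n, phi = 500, 5, 0.3
        mu = rng.lognormal(4, 1, G)
        counts = pd.DataFrame(
            np.column_stack([nb_draw(rng, mu, phi) for _ in range(2 * n)]),
            index=[f"g{i}" for i in range(G)],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        res = diffabund.nb_wald_test(counts, ["A"] * n + ["B"] * n)
        assert (res.qvalue < 0.05).mean() <= 0.05

    def test_reference_level_sets_sign(self):
        rng = np.random.default_rng(5)
        mu = np.full(50, 100.0)
        A = np.column_stack([nb_draw(rng, mu, 0.1) for _ in range(4)])
        B = np.column_stack([nb_draw(rng, mu * 4, 0.1) for _ in range(4)])
        counts = pd.DataFrame(np.hstack([A, B]), columns=[f"s{i}" for i in range(8)])
        labels = ["ctl"] * 4 + ["hi"] * 4
        # unit size factors: a global shift would otherwise be normalized away
        sf = pd.Series(1.0, index=counts.columns)
        res = diffabund.nb_wald_test(counts, labels, sf=sf, reference="ctl")
        assert res.log2FC.median() == pytest.approx(2.0, abs=0.3)
        flipped = diffabund.nb_wald_test(counts, labels, sf=sf, reference="hi")
        np.testing.assert_allclose(res.log2FC, -flipped.log2FC, rtol=1e-5, atol=1e-8)

    def test_independent_filtering_excludes_low_means(self):
        counts = pd.DataFrame(
            {f"s{i}": [0, 300] for i in range(6)}, index=["low", "high"]
        )
        counts.iloc[0, 0] = 1  # mean well below 1
        res = diffabund.nb_wald_test(counts, ["A"] * 3 + ["B"] * 3)
        assert not res.loc["low", "tested"]
        assert np.isnan(res.loc["low", "qvalue"])


class TestBh:
    def test_monotone_under_pvalue_increase(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200) ** 3
        q1 = diffabund.bh_adjust(p)
        p2 = np.clip(p + rng.uniform(0, 0.2, size=200), 0, 1)
        q2 = diffabund.bh_adjust(p2)
        sig1 = set(np.nonzero(q1 < 0.05)[0])
        sig2 = set(np.nonzero(q2 < 0.05)[0])
        # element-wise larger p-values can only shrink the significant set
        assert sig2 <= sig1 or (q2 >= q1 - 1e-12).all()


class TestImpulse:
    days = np.repeat(np.arange(0, 43, 7), 2).astype(float)

    def test_constant_counts_reduce_to_constant_model(self):
        y = np.full(len(self.days), 30)
        fit = diffabund.impulse_fit(y, self.days, dispersion=0.3)
        assert fit.loglik_impulse == pytest.approx(fit.loglik_constant, abs=1e-6)
        assert fit.lrt_p > 0.5

    def test_equal_amplitudes_are_constant_mean(self):
        mu = diffabund.impulse_mean(self.days, 20, 20, 20, 10, 30, 1.0)
        np.testing.assert_allclose(mu, 20.0, rtol=1e-12)

    def test_needs_four_timepoints(self):
        with pytest.raises(ValueError):
            diffabund.impulse_fit([1, 2, 3], [0.0, 7.0, 14.0], dispersion=0.3)

    def test_up_pulse_transition_time_recovered(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            days = np.repeat(np.arange(0, 43, 7), 3).astype(float)
            mu = diffabund.impulse_mean(days, 10, 200, 200, 14, 30, 1.0)
            y = nb_draw(rng, mu, 0.3)
            fit = diffabund.impulse_fit(y, days, dispersion=0.3)
            errs.append(abs(fit.t1 - 14))
        assert np.median(errs) <= 3.0

    def test_screen_orders_pulsed_above_flat(self):
        rng = np.random.default_rng(2)
        days = np.repeat(np.arange(0, 43, 7), 3).astype(float)
        pulsed = nb_draw(rng, diffabund.impulse_mean(days, 10, 300, 300, 14, 30, 1.0), 0.3)
        flat = nb_draw(rng, np.full(len(days), 50.0), 0.3)
        counts = pd.DataFrame(
            [pulsed, flat], index=["pulsed", "flat"],
            columns=[f"s{i}" for i in range(len(days))],
        )
        res = diffabund.impulse_screen(
            counts, days, sf=pd.Series(1.0, index=counts.columns), dispersion=0.3
        )
        assert res.loc["pulsed", "pvalue"] < 1e-4 < res.loc["flat", "pvalue"]


class TestPrerankedEs:
    def ranking(self, n=12, seed=1):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.normal(0, 1, n))[::-1]
        return pd.Series(vals, index=[f"g{i}" for i in range(n)])

    def test_top_k_set_is_maximal_by_enumeration(self):
        scores = self.ranking(10)
        k = 3
        top = set(scores.index[:k])
        es_top = diffabund.preranked_es(scores, top, n_perm=10, seed=0).es
        for combo in combinations(scores.index, k):
            es = diffabund.preranked_es(scores, set(combo), n_perm=10, seed=0).es
            assert es_top >= es - 1e-12
        assert es_top > 0

    def test_full_ranking_set_is_degenerate(self):
        scores = self.ranking(12)
        full = diffabund.preranked_es(scores, set(scores.index), n_perm=50, seed=0)
        best_proper = diffabund.preranked_es(
            scores, set(scores.index[:3]), n_perm=50, seed=0
        )
        assert abs(full.es) <= abs(best_proper.es)

    def test_weight_zero_bounds(self):
        rng = np.random.default_rng(4)
        scores = self.ranking(50)
        for _ in range(10):
            members = set(rng.choice(scores.index, 7, replace=False))
            es = diffabund.preranked_es(scores, members, weight=0.0, n_perm=10, seed=0).es
            assert -1.0 <= es <= 1.0

    def test_permutation_p_deterministic_and_corrected(self):
        scores = self.ranking(100, seed=2)
        members = set(scores.index[10:16])
        r1 = diffabund.preranked_es(scores, members, n_perm=500, seed=42)
        r2 = diffabund.preranked_es(scores, members, n_perm=500, seed=42)
        assert r1.pvalue == r2.pvalue and 0 < r1.pvalue <= 1

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            diffabund.preranked_es(self.ranking(5), {"absent"}, n_perm=10)

    def test_duplicate_genes_rejected(self):
        s = pd.Series([1.0, 2.0], index=["g", "g"])
        with pytest.raises(ValueError):
            diffabund.preranked_es(s, {"g"}, n_perm=10)


class TestPca:
    def test_identical_samples_zero_variance(self):
        cpm = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        coords, _, varexp = diffabund.pca_project(cpm, n_components=2)
        np.testing.assert_allclose(coords, 0.0, atol=1e-12)
        np.testing.assert_allclose(varexp, 0.0, atol=1e-12)

    def test_rank_one_line_explains_everything(self):
        t = np.array([0.0, 1.0, 2.0, 5.0])
        direction = np.array([1.0, -2.0, 0.5])
        X = pd.DataFrame(np.outer(direction, t))
        _, _, varexp = diffabund.pca_project(X, n_components=2)
        assert varexp[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        coords, loadings, varexp = diffabund.pca_project(X, n_components=2)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=1, keepdims=True)
        cov = Xc @ Xc.T  # gene × gene scatter
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for j in range(2):
            ref = v[:, order[j]]
            got = loadings.iloc[:, j].to_numpy()
            assert abs(abs(ref @ got)) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            varexp, w[order[:2]] / w.sum(), rtol=1e-9
        )
        # sign convention: dominant loading positive
        for j in range(2):
            col = loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            diffabund.pca_project(pd.DataFrame({"a": [1.0, 2.0]}), n_components=2)


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg2\n")
    sets = diffabund.read_gmt(path)
    assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g2"}}
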
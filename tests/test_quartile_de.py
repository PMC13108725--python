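import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tamscreen.quartile_de import (
    call_de,
    estimate_dispersion,
    filter_genes,
    run_quartile_de,
    shrink_lfc,
    size_factors,
    wald_test,
)


def nb_counts(rng, mu, alpha):
    """NB draws at mean mu (array) and dispersion alpha."""
    if alpha <= 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu))


def planted_matrix(rng, n_genes=2000, n_planted=20, lfc=3.0, n_per_group=6,
                   alpha=0.05):
    """6v6 NB count matrix with the first n_planted genes shifted by lfc."""
    base = 2.0 ** rng.uniform(3, 8, size=n_genes)
    mu = np.tile(base[:, None], (1, 2 * n_per_group))
    mu[:n_planted, n_per_group:] *= 2.0**lfc
    counts = nb_counts(rng, mu, alpha)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"B{i}" for i in range(n_per_group)] + [f"T{i}" for i in range(n_per_group)]
    groups = ["bottom"] * n_per_group + ["top"] * n_per_group
    return pd.DataFrame(counts, index=genes, columns=samples), groups


class TestFilterGenes:
    def test_total_count_rule(self):
        m = pd.DataFrame({"s1": [1], "s2": [1], "s3": [1]}, index=["g"])
        kept, removed = filter_genes(m)
        assert removed == ["g"]  # total 3 <= 3

    def test_detection_boundary_inclusive(self):
        m = pd.DataFrame([[0, 0, 5, 5]], index=["g"], columns=list("abcd"))
        kept, removed = filter_genes(m)
        assert list(kept.index) == ["g"]  # detected in exactly 50%

    def test_constructed_toy_keeps_exactly_six(self, rng):
        rows = []
        names = []
        for i in range(6):  # clearly passing genes
            rows.append([10, 12, 9, 11])
            names.append(f"ok{i}")
        rows += [[1, 1, 1, 0],      # total 3
                 [0, 0, 0, 9],      # detected 25%
                 [2, 0, 0, 1],      # total 3
                 [5, 0, 0, 0]]      # detected 25%
        names += ["fail1", "fail2", "fail3", "fail4"]
        m = pd.DataFrame(rows, index=names, columns=list("abcd"))
        kept, removed = filter_genes(m)
        assert len(kept) == 6 and len(removed) == 4

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_genes(pd.DataFrame())


class TestSizeFactors:
    def test_hand_example(self):
        sf = size_factors(pd.DataFrame([[2, 4], [4, 8]]))
        np.testing.assert_allclose(sf, [0.7071, 1.4142], atol=1e-4)

    def test_identical_samples_get_unit_factors(self):
        sf = size_factors(pd.DataFrame([[5, 5], [9, 9], [2, 2]]))
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_scaling_equivariance(self, rng):
        m = rng.poisson(50, size=(100, 4)) + 1
        sf = size_factors(m)
        m2 = m.astype(float).copy()
        m2[:, 2] *= 2.0
        sf2 = size_factors(m2)
        # size factors are defined up to a common scale: doubling one
        # sample's counts doubles its factor relative to every other sample
        np.testing.assert_allclose(
            (sf2[2] / sf2) / (sf[2] / sf), [2.0, 2.0, 1.0, 2.0], rtol=1e-9
        )

    def test_gene_reordering_invariance(self, rng):
        m = pd.DataFrame(rng.poisson(30, size=(50, 3)) + 1)
        sf1 = size_factors(m)
        sf2 = size_factors(m.sample(frac=1.0, random_state=1))
        np.testing.assert_allclose(sf1, sf2)

    def test_poscounts_fallback_when_no_all_positive_gene(self, rng, caplog):
        m = rng.poisson(20, size=(40, 4))
        m[np.arange(40), np.arange(40) % 4] = 0  # every gene has a zero
        with caplog.at_level("INFO", logger="tamscreen"):
            sf = size_factors(m)
        assert np.all(sf > 0)

    def test_matches_reference_median_of_ratios(self, rng):
        # independent oracle: pydeseq2's median-of-ratios normalization
        from pydeseq2.preprocessing import deseq2_norm

        # odd gene count: the median ratio is a single element, so the
        # log-space median pydeseq2 takes agrees exactly with ours
        m = pd.DataFrame(rng.poisson(60, size=(201, 8)) + 1)
        _, sf_ref = deseq2_norm(m.T)  # pydeseq2 is samples x genes
        np.testing.assert_allclose(size_factors(m), np.asarray(sf_ref), rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        m = pd.DataFrame([[1, 0], [2, 0]], columns=["good", "dead"])
        with pytest.raises(ValueError, match="dead"):
            size_factors(m)


class TestDispersion:
    def test_poisson_counts_hit_the_floor(self, rng):
        mu = 2.0 ** rng.uniform(4, 8, size=500)
        counts = rng.poisson(np.tile(mu[:, None], (1, 50)))
        disp = estimate_dispersion(counts, np.ones(50))
        assert np.median(disp) < 0.01

    def test_nb_dispersion_recovered_within_band(self, rng):
        medians = []
        for _ in range(10):
            mu = 2.0 ** rng.uniform(5, 9, size=400)
            counts = nb_counts(rng, np.tile(mu[:, None], (1, 20)), 0.2)
            disp = estimate_dispersion(counts, np.ones(20))
            medians.append(np.median(disp))
        assert 0.1 <= np.median(medians) <= 0.4

    def test_constant_gene_floored(self):
        counts = np.tile([[7]], (1, 10)).repeat(20, axis=0)
        disp = estimate_dispersion(counts, np.ones(10))
        assert np.all(disp[0] <= 1e-6)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_dispersion(rng.poisson(10, (5, 2)), np.ones(2))


class TestWaldTest:
    def test_identical_groups_give_null_results(self, rng):
        block = rng.poisson(100, size=(50, 4))
        counts = pd.DataFrame(np.hstack([block, block]),
                              index=[f"g{i}" for i in range(50)])
        sf = np.ones(8)
        disp = np.full(50, 0.05)
        res = wald_test(counts, sf, disp, ["a"] * 4 + ["b"] * 4)
        assert np.nanmax(np.abs(res["lfc_mle"])) < 1e-6
        assert np.nanmin(res["p_raw"]) > 0.99

    def test_planted_lfc_recovered(self, rng):
        means = []
        for _ in range(10):
            counts, groups = planted_matrix(rng, n_genes=300, n_planted=30, lfc=2.0)
            sf = size_factors(counts)
            disp = estimate_dispersion(counts, sf)
            res = wald_test(counts, sf, disp, groups)
            means.append(res["lfc_mle"].iloc[:30].mean())
        assert np.mean(means) == pytest.approx(2.0, abs=0.3)

    def test_all_zero_group_stays_finite(self, rng):
        counts = pd.DataFrame(
            [[0, 0, 0, 50, 60, 55]] + rng.poisson(30, (30, 6)).tolist(),
            index=[f"g{i}" for i in range(31)],
        )
        res = wald_test(counts, np.ones(6), np.full(31, 0.05), ["a"] * 3 + ["b"] * 3)
        assert np.isfinite(res["lfc_mle"].iloc[0])
        assert res["lfc_mle"].iloc[0] > 3
        assert res["p_raw"].iloc[0] < 0.01

    def test_null_permutation_pvalues_uniform(self, rng):
        counts, _ = planted_matrix(rng, n_genes=2000, n_planted=0)
        sf = size_factors(counts)
        disp = estimate_dispersion(counts, sf)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        rng.shuffle(labels)
        res = wald_test(counts, sf, disp, labels)
        p = res["p_raw"].dropna()
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05


class TestShrinkage:
    def frame(self, lfc, se):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(lfc))],
             "base_mean": 100.0, "lfc_mle": lfc, "se": se,
             "wald": np.asarray(lfc) / np.asarray(se),
             "p_raw": 0.5, "converged": True}
        )

    def test_precise_estimates_unshrunk(self):
        res = shrink_lfc(self.frame([2.0] * 5 + [0.0] * 10, [1e-6] * 15))
        assert res["lfc_shrunken"].iloc[0] == pytest.approx(2.0, rel=1e-3)

    def test_zero_mle_stays_zero(self):
        res = shrink_lfc(self.frame([0.0] * 12, [0.5] * 12))
        assert (res["lfc_shrunken"] == 0).all()

    def test_shrinkage_never_inflates_magnitude(self, rng):
        lfc = rng.normal(0, 2, 200)
        se = rng.uniform(0.1, 2, 200)
        res = shrink_lfc(self.frame(lfc, se))
        assert np.all(np.abs(res["lfc_shrunken"]) <= np.abs(res["lfc_mle"]) + 1e-9)

    def test_null_simulation_reduces_average_magnitude(self, rng):
        lfc = rng.normal(0, 0.5, 500)  # pure noise around zero
        se = np.full(500, 0.5)
        res = shrink_lfc(self.frame(lfc, se))
        assert res["lfc_shrunken"].abs().mean() < res["lfc_mle"].abs().mean()

    def test_larger_se_shrinks_proportionally_more(self, rng):
        lfc = np.full(100, 1.5)
        se = np.linspace(0.1, 2.0, 100)
        res = shrink_lfc(self.frame(rng.normal(0, 1, 100), se).assign(lfc_mle=lfc))
        shrunk = res["lfc_shrunken"].to_numpy()
        assert np.all(np.diff(shrunk) <= 1e-12)  # monotone decreasing in se


class TestCallDe:
    def test_dual_threshold(self):
        res = pd.DataFrame(
            {"gene": ["a", "b", "c"], "p_raw": [0.0001, 0.0001, 0.9],
             "lfc_shrunken": [2.0, 0.5, 3.0]}
        )
        out = call_de(res)
        assert out["significant"].tolist() == [True, False, False]

    def test_no_small_p_no_calls(self, rng):
        res = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(50)],
             "p_raw": rng.uniform(0.5, 1, 50), "lfc_shrunken": 5.0}
        )
        assert call_de(res)["significant"].sum() == 0


class TestFullStage:
    def test_power_fdr_and_auroc_on_planted_run(self, rng):
        powers, false_rates, aurocs = [], [], []
        for _ in range(5):
            counts, groups = planted_matrix(rng)
            top = {c for c, g in zip(counts.columns, groups) if g == "top"}
            bottom = set(counts.columns) - top
            res = run_quartile_de(counts, top, bottom)
            planted = res["gene"].str.slice(1).astype(int) < 20
            powers.append(res.loc[planted, "significant"].mean())
            false_rates.append(res.loc[~planted, "significant"].mean())
            score = res["p_raw"].fillna(1.0)
            ranks = stats.rankdata(-score)
            n1, n0 = planted.sum(), (~planted).sum()
            auroc = (ranks[planted].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
            aurocs.append(auroc)
        assert np.mean(powers) >= 0.8
        assert np.mean(false_rates) <= 0.05
        assert np.mean(aurocs) > 0.95
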
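"""Differential-expression tests: exact enumeration, beta approximation,
routing, BH adjustment and result filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from xbcount.detest import (
    beta_approx_test,
    bh_adjust,
    exact_test,
    filter_results,
    null_pooled_params,
    run_de,
)
from xbcount.model import DelaporteParams


def exact_oracle(x: int, y: int, pA: DelaporteParams, pB: DelaporteParams) -> float:
    """Brute-force double loop with independently coded pmfs."""

    def dela_pmf(t: int, p: DelaporteParams) -> float:
        k = np.arange(t + 1)
        return float(
            (stats.nbinom.pmf(k, p.alpha, 1 / (p.beta + 1)) * stats.poisson.pmf(t - k, p.lam)).sum()
        )

    n = x + y
    probs = np.array([dela_pmf(a, pA) * dela_pmf(n - a, pB) for a in range(n + 1)])
    obs = probs[x]
    return float(probs[probs <= obs * (1 + 1e-8)].sum() / probs.sum())


class TestExactTest:
    def test_symmetric_observation_gives_one(self):
        p = DelaporteParams(2, 2, 1)
        assert exact_test(10, 10, p, p) == 1.0

    def test_zero_total_convention(self):
        p = DelaporteParams(2, 2, 1)
        assert exact_test(0, 0, p, p) == 1.0

    def test_against_bruteforce_oracle(self):
        p = DelaporteParams(2, 2, 1)
        assert exact_test(15, 5, p, p) == pytest.approx(exact_oracle(15, 5, p, p), abs=1e-12)

    @pytest.mark.parametrize(
        "pA,pB",
        [
            (DelaporteParams(2, 2, 1), DelaporteParams(2, 2, 1)),
            (DelaporteParams(5, 0.8, 0.5), DelaporteParams(3, 1.5, 2)),
            (DelaporteParams(1, 4, 0), DelaporteParams(8, 0.5, 3)),
        ],
    )
    def test_swap_symmetry(self, pA, pB):
        for x, y in [(12, 3), (0, 7), (5, 5)]:
            assert exact_test(x, y, pA, pB) == pytest.approx(
                exact_test(y, x, pB, pA), rel=1e-10
            )

    def test_underflowing_observation_uses_logspace(self):
        # extreme split far in the tail of both laws
        p = DelaporteParams(2, 1, 0.5)
        val = exact_test(1400, 2, p, p)
        assert 0.0 < val < 1.0


class TestBetaApproxTest:
    def test_matches_independent_formula_evaluation(self):
        x, y, n1, n2 = 60, 40, 3, 3
        z = x + y
        mu = z / (n1 + n2)
        a = n1 * mu / (1 + n1 / mu)
        b = n2 * mu / (1 + n2 / mu)
        med = stats.beta.ppf(0.5, a, b)
        k = (x + 0.5) / z if (x + 0.5) / z < med else (x - 0.5) / z
        expected = min(2 * k ** (a - 1) * (1 - k) ** (b - 1) / special.beta(a, b), 1.0)
        assert beta_approx_test(x, y, n1, n2) == pytest.approx(expected, rel=1e-10)

    def test_symmetric_counts_straddle_gives_one(self):
        assert beta_approx_test(50, 50, 3, 3) == 1.0

    def test_density_above_one_clamps(self):
        # near-central observation of a concentrated beta: density >> 1
        assert beta_approx_test(301, 299, 3, 3) == 1.0

    def test_zero_total_convention(self):
        assert beta_approx_test(0, 0, 3, 3) == 1.0

    @pytest.mark.parametrize("z", [50, 100, 500])
    def test_monotone_in_imbalance(self, z):
        ps = [beta_approx_test(z // 2 + d, z - z // 2 - d, 3, 3) for d in range(0, z // 2, max(z // 20, 1))]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_rank_agreement_with_exact_near_poisson(self):
        # the approximation assumes Poisson-scale spread; under near-Poisson
        # dispersion its ranking matches the exact test's
        rng = np.random.default_rng(0)
        pe, pb = [], []
        for _ in range(300):
            mu = rng.uniform(20, 140)
            lam = 0.02 * mu
            phi = 0.002
            fold = rng.choice([1.0, 1.2, 1.5, 2.0])
            x = int(rng.poisson(3 * mu * fold))
            y = int(rng.poisson(3 * mu))
            if not 100 <= x + y <= 2000:
                continue
            mu0 = (x + y) / 6.0 - lam
            pA = null_pooled_params(mu0, max(phi * mu0, 1e-8), lam, 3)
            pe.append(exact_test(x, y, pA, pA))
            pb.append(beta_approx_test(x, y, 3, 3))
        rho = stats.spearmanr(pe, pb).statistic
        assert rho >= 0.95


class TestBhAdjust:
    def test_hand_computation(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.33]) == pytest.approx([0.33])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _toy_dataset(rng, n_genes=5, fold_gene=0, fold=10.0, base=40):
    mu = np.full(n_genes, float(base))
    X = rng.poisson(mu[:, None], size=(n_genes, 6)).astype(float)
    X[fold_gene, 3:] = rng.poisson(base * fold, size=3)
    B = rng.poisson(1.0, size=(n_genes, 6))
    idx = [f"g{i}" for i in range(n_genes)]
    cols = list("abcdef")
    return (
        pd.DataFrame(X.astype(int), index=idx, columns=cols),
        pd.DataFrame(B, index=idx, columns=cols),
    )


class TestRunDe:
    GROUPS = ["A", "A", "A", "B", "B", "B"]

    def test_changed_gene_attains_smallest_p_exact_path(self):
        X, B = _toy_dataset(np.random.default_rng(0))
        res = run_de(X, B, self.GROUPS, big_count=10**9)
        assert res["pval"].idxmin() == "g0"
        assert (res["test"] == "exact").all()

    def test_route_consistency_for_well_separated_gene(self):
        X, B = _toy_dataset(np.random.default_rng(1), base=300)
        exact = run_de(X, B, self.GROUPS, big_count=10**9)
        beta = run_de(X, B, self.GROUPS, big_count=0)
        assert exact["pval"].idxmin() == beta["pval"].idxmin() == "g0"

    def test_null_data_yields_no_discoveries(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.poisson(5, size=(50, 6)),
                index=[f"g{i}" for i in range(50)],
                columns=list("abcdef"),
            )
            res = run_de(X, X.copy(), self.GROUPS)
            if (res["padj"] < 0.1).any():
                flagged += 1
        assert flagged <= 1  # >= 95% of seeded runs clean

    def test_zero_count_gene_reported_inert(self):
        X, B = _toy_dataset(np.random.default_rng(2))
        X.iloc[3] = 0
        B.iloc[3] = 0
        res = run_de(X, B, self.GROUPS)
        assert res.loc["g3", "pval"] == 1.0
        assert res.loc["g3", "padj"] == 1.0
        assert res.loc["g3", "test"] == "none"

    def test_exact_path_null_calibration(self):
        from xbcount.simulate import SimConfig, simulate_experiment, truth_frames

        truth = simulate_experiment(SimConfig(n_genes=2000, seed=5), rep=0)
        X, B, _ = truth_frames(truth)
        res = run_de(X, B, truth.groups)
        sel = (res["test"] == "exact").to_numpy() & ~truth.de
        frac = (res["pval"].to_numpy()[sel] < 0.05).mean()
        assert 0.01 <= frac <= 0.10

    def test_mle_route_ranks_changed_gene_first(self):
        X, B = _toy_dataset(np.random.default_rng(4))
        res = run_de(X, B, self.GROUPS, est_method="mle")
        assert res["pval"].idxmin() == "g0"

    def test_dispersion_share_modes(self):
        X, B = _toy_dataset(np.random.default_rng(5))
        for mode in ("maximum", "fit-only", "gene-est"):
            res = run_de(X, B, self.GROUPS, dispersion_share=mode)
            assert res["pval"].idxmin() == "g0"
        with pytest.raises(ValueError):
            run_de(X, B, self.GROUPS, dispersion_share="bogus")

    def test_group_validation(self):
        X, B = _toy_dataset(np.random.default_rng(3))
        with pytest.raises(ValueError):
            run_de(X, B, ["A"] * 6)
        with pytest.raises(ValueError):
            run_de(X, B, ["A", "B", "C", "A", "B", "C"])
        with pytest.raises(ValueError):
            run_de(X, B.iloc[:3], self.GROUPS)


class TestFilterResults:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {
                "mean_A": [100.0, 100.0, 100.0, 5.0],
                "mean_B": [300.0, 300.0, 110.0, 20.0],
                "log2FC": np.log2([3.0, 3.0, 1.1, 4.0]),
                "pval": [0.001, 0.2, 0.001, 0.001],
                "padj": [0.01, 0.5, 0.01, 0.01],
                "test": ["exact"] * 4,
            },
            index=["keep", "high_p", "low_fc", "low_expr"],
        )

    def test_single_qualifying_gene(self):
        out = filter_results(self._table(), fc_min=1.5, expr_quantile=0.5, padj_max=0.1)
        assert list(out.index) == ["keep"]

    def test_identity_filter(self):
        table = self._table()
        out = filter_results(table, fc_min=0, expr_quantile=0, padj_max=1.01)
        assert len(out) == len(table)

    def test_padj_zero_empties(self):
        assert filter_results(self._table(), padj_max=0).empty

    def test_downregulation_counts_as_fold_change(self):
        table = self._table()
        table.loc["keep", "log2FC"] = -np.log2(3.0)
        out = filter_results(table, fc_min=1.5, expr_quantile=0.5, padj_max=0.1)
        assert "keep" in out.index
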
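import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodbrain.concordance import (
    blood_brain_matrix,
    correlate,
    correlation_power,
    fisher_ci,
    interregion_matrix,
    measure_by_tissue,
    pvalue_from_r,
    results_to_frame,
    score_trait_correlations,
    sensitivity_compare,
)
from bloodbrain.episcore import project_scores
from bloodbrain.simulate import SimulationConfig, simulate_cohort


def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Covariance over sigma_x*sigma_y, accumulated element by element."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestCorrelate:
    def test_perfect_linearity(self):
        res = correlate([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)

    def test_printed_pair_r061_n14(self):
        assert round(pvalue_from_r(0.61, 14), 2) == 0.02

    def test_brute_force_oracle_50_points(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        res = correlate(x, y)
        assert res.r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, np.nan, 3.0, 8.0, 10.0]
        res = correlate(x, y)
        assert res.n == 3

    def test_undefined_small_n(self):
        res = correlate([1, 2], [3, 4])
        assert not res.defined
        assert math.isnan(res.r)

    def test_undefined_zero_variance(self):
        res = correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined
        assert res.note == "zero variance"

    def test_spearman_is_pearson_on_ranks(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=30), rng.normal(size=30)
        from scipy.stats import rankdata

        res = correlate(x, y, method="spearman")
        assert res.r == pytest.approx(brute_force_pearson(rankdata(x), rankdata(y)), abs=1e-12)

    @given(st.sampled_from(["exp", "cube", "affine"]))
    @settings(max_examples=10, deadline=None)
    def test_spearman_monotone_invariance(self, transform):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        fx = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3 * v + 1}[transform](x)
        r0 = correlate(x, y, method="spearman").r
        r1 = correlate(fx, y, method="spearman").r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_exact_spearman_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        res = correlate(x, y, method="spearman", exact=True)
        # independent enumeration oracle: 16 of the 120 permutations reach
        # |rho| >= 0.8 at n = 5
        assert res.p == pytest.approx(16 / 120, abs=1e-12)

    def test_fisher_ci_contains_r(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x, y = rng.normal(size=15), rng.normal(size=15)
            res = correlate(x, y)
            assert res.ci_low <= res.r <= res.ci_high

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2])

    def test_unknown_method_error(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2, 3], method="kendall")


class TestPrintedPValues:
    # frozen: every printed (r, n, P) triple recomputes analytically
    @pytest.mark.parametrize(
        "r,n,printed,decimals",
        [
            (0.61, 14, 0.02, 2),
            (0.5, 14, 0.07, 2),
            (-0.72, 14, 0.004, 3),
            (0.55, 14, 0.04, 2),
            (-0.65, 9, 0.06, 2),
            (0.56, 9, 0.12, 2),
            (0.62, 14, 0.02, 2),
        ],
    )
    def test_analytic_p_recovery(self, r, n, printed, decimals):
        assert round(pvalue_from_r(r, n), decimals) == printed


def _score_pivot(cohort, trait="smoking"):
    frames = []
    for tissue, m in cohort.matrices.items():
        frames.append(project_scores(m, cohort.weights[trait]))
    scores = pd.concat(frames, ignore_index=True)[["sample_id", "score"]]
    return measure_by_tissue(scores, cohort.sheet, value_col="score")


class TestBloodBrainMatrix:
    def test_ba35_missing_gives_n13(self):
        cohort = simulate_cohort(SimulationConfig(seed=5))
        pivot = _score_pivot(cohort)
        results = {r.var_y.split(":")[1]: r for r in blood_brain_matrix(pivot, "smoking")}
        assert results["BA35"].n == 13
        for region in ("BA17", "BA20/21", "BA24", "BA46"):
            assert results[region].n == 14

    def test_rho_zero_large_n(self):
        cfg = SimulationConfig(seed=6, n_individuals=2000, regions=("blood", "BA46"),
                               rho_region={"BA46": 0.0}, sigma_cpg=0.0, missing_ba35=False,
                               n_never_smokers=200, n_current_smokers=600, n_missing_cigarettes=100)
        cohort = simulate_cohort(cfg)
        pivot = _score_pivot(cohort)
        res = blood_brain_matrix(pivot, "smoking", regions=("BA46",))[0]
        assert abs(res.r) < 0.05

    def test_blood_with_itself_r1(self):
        cohort = simulate_cohort(SimulationConfig(seed=7))
        pivot = _score_pivot(cohort)
        res = correlate(pivot["blood"], pivot["blood"])
        assert res.r == pytest.approx(1.0)

    def test_no_blood_column_error(self):
        pivot = pd.DataFrame({"BA17": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="blood"):
            blood_brain_matrix(pivot, "smoking")


class TestScoreTraitCorrelations:
    def test_pack_years_n9_when_5_missing(self):
        cohort = simulate_cohort(SimulationConfig(seed=8))
        pivot = _score_pivot(cohort)
        results = score_trait_correlations(pivot, cohort.phenotypes, "smoking")
        pack = [r for r in results if r.var_y == "pack_years"]
        assert pack and all(r.n == 9 or (r.var_x.endswith("BA35") and r.n == 8) for r in pack)
        non_ba35 = [r for r in pack if not r.var_x.endswith("BA35")]
        assert all(r.n == 9 for r in non_ba35)

    def test_printed_pair_r065_n9(self):
        assert round(pvalue_from_r(-0.65, 9), 2) == 0.06

    def test_constant_phenotype_undefined(self):
        pivot = pd.DataFrame({"blood": [0.1, 0.2, 0.3, 0.4]},
                             index=pd.Index([f"I{i}" for i in range(4)], name="individual_id"))
        pheno = pd.DataFrame({"individual_id": [f"I{i}" for i in range(4)], "hdl": [1.5] * 4})
        results = score_trait_correlations(pivot, pheno, "HDL")
        assert not results[0].defined


class TestInterregionMatrix:
    def test_identical_vectors_offdiag_1(self):
        v = [0.1, 0.5, 0.9, 0.3, 0.7]
        pivot = pd.DataFrame({"BA17": v, "BA46": v})
        mat = interregion_matrix(pivot)
        assert mat.r.loc["BA17", "BA46"] == pytest.approx(1.0)

    def test_exchangeable_rho_05_recovered(self):
        cfg = SimulationConfig(
            seed=9, n_individuals=2000, sigma_cpg=0.0, missing_ba35=False,
            rho_region={r: 0.5 for r in ("BA17", "BA20/21", "BA24", "BA35", "BA46")},
            rho_interregion=0.5,
            n_never_smokers=200, n_current_smokers=600, n_missing_cigarettes=100,
        )
        cohort = simulate_cohort(cfg)
        pivot = _score_pivot(cohort, trait="HDL")
        # Pearson recovers the generator's target directly; Spearman of a
        # rho=0.5 Gaussian converges to (6/pi)*asin(rho/2) ~ 0.483 instead
        mat = interregion_matrix(pivot, method="pearson")
        off = [mat.r.loc[a, b] for a in mat.labels for b in mat.labels if a != b]
        assert all(abs(r - 0.5) < 0.05 for r in off)
        mat_s = interregion_matrix(pivot, method="spearman")
        expected_s = (6 / math.pi) * math.asin(0.25)
        off_s = [mat_s.r.loc[a, b] for a in mat_s.labels for b in mat_s.labels if a != b]
        assert all(abs(r - expected_s) < 0.05 for r in off_s)

    def test_5x5_unit_diagonal(self):
        cohort = simulate_cohort(SimulationConfig(seed=10))
        pivot = _score_pivot(cohort)
        mat = interregion_matrix(pivot)
        assert mat.r.shape == (5, 5)
        assert np.allclose(np.diag(mat.r.to_numpy()), 1.0)
        assert np.allclose(mat.r.to_numpy(), mat.r.to_numpy().T)

    def test_blood_augmented_6x6(self):
        cohort = simulate_cohort(SimulationConfig(seed=10))
        pivot = _score_pivot(cohort)
        mat = interregion_matrix(pivot, include_blood=True)
        assert mat.r.shape == (6, 6)

    def test_single_region_error(self):
        pivot = pd.DataFrame({"BA17": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            interregion_matrix(pivot)


class TestSensitivityCompare:
    def test_gaussian_near_equality(self):
        rng = np.random.default_rng(14)
        chol = np.linalg.cholesky([[1, 0.6], [0.6, 1]])
        xy = rng.standard_normal((2000, 2)) @ chol.T
        rp = correlate(xy[:, 0], xy[:, 1], var_x="a", var_y="b")
        rs = correlate(xy[:, 0], xy[:, 1], method="spearman", var_x="a", var_y="b")
        assert abs(rp.r - rs.r) < 0.05
        df = sensitivity_compare([rp], [rs])
        assert df["top_agree"].all()

    def test_outlier_robustness(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=30)
        y = 0.6 * x + 0.8 * rng.normal(size=30)
        rp0 = correlate(x, y).r
        rs0 = correlate(x, y, method="spearman").r
        x2, y2 = x.copy(), y.copy()
        x2[0], y2[0] = 10.0, -10.0  # gross outlier
        rp1 = correlate(x2, y2).r
        rs1 = correlate(x2, y2, method="spearman").r
        assert abs(rs1 - rs0) < abs(rp1 - rp0)

    def test_identical_inputs_identical_ranks(self):
        rng = np.random.default_rng(16)
        results_p, results_s = [], []
        for i in range(4):
            x, y = rng.normal(size=20), rng.normal(size=20)
            results_p.append(correlate(x, y, var_x=f"m{i}", var_y="t"))
            results_s.append(correlate(x, y, var_x=f"m{i}", var_y="t"))  # same method: same r
        df = sensitivity_compare(results_p, results_s)
        assert (df["rank_pearson"] == df["rank_spearman"]).all()

    def test_no_overlap_error(self):
        r1 = correlate([1, 2, 3, 4], [2, 3, 1, 4], var_x="a", var_y="b")
        r2 = correlate([1, 2, 3, 4], [2, 3, 1, 4], var_x="c", var_y="d")
        with pytest.raises(ValueError):
            sensitivity_compare([r1], [r2])


class TestCorrelationPower:
    def test_size_under_null(self):
        out = correlation_power(20, 0.0, alpha=0.05, n_sims=2000, seed=1)
        assert abs(out["power_mc"] - 0.05) <= 2 * math.sqrt(0.05 * 0.95 / 2000) + 1e-9

    def test_mc_matches_fisher_closed_form(self):
        out = correlation_power(14, 0.5, alpha=0.05, n_sims=3000, seed=2)
        assert abs(out["power_mc"] - out["power_fisher"]) <= 3 * out["se_mc"] + 0.02

    def test_monotone_in_n(self):
        powers = [correlation_power(n, 0.5, n_sims=1500, seed=3)["power_mc"] for n in (10, 20, 40, 80)]
        assert powers == sorted(powers)

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            correlation_power(14, 1.0)


def test_results_to_frame_counts_tests():
    rng = np.random.default_rng(17)
    results = [correlate(rng.normal(size=10), rng.normal(size=10), var_x=f"v{i}", var_y="t") for i in range(3)]
    df = results_to_frame(results)
    assert (df["n_tests"] == 3).all()
    assert set(df.columns) >= {"var_x", "var_y", "method", "r", "n", "p", "ci_low", "ci_high"}
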
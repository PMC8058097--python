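import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoage.association import (
    AgeAssociationCascade,
    SeparationError,
    bh_adjust,
    covariate_select,
    fit_firth,
    fit_linear,
    fit_logistic,
    rank_group_tests,
)


def _bh_brute_force(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 25)))
            assert np.allclose(bh_adjust(p), _bh_brute_force(p))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
    def test_permutation_invariance_and_bounds(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), adj[perm])


class TestCovariateSelect:
    def _clin(self, missing, n=100):
        vals = ["a", "b"] * (n // 2)
        col = pd.Series(vals[:n], dtype=object)
        col.iloc[:missing] = np.nan
        return pd.DataFrame({"stage": col, "flat": ["x"] * n})

    def test_nine_percent_missing_kept(self):
        assert covariate_select(self._clin(9), ["stage"]) == ["stage"]

    def test_ten_percent_missing_dropped(self):
        assert covariate_select(self._clin(10), ["stage"]) == []

    def test_constant_covariate_dropped(self):
        assert covariate_select(self._clin(0), ["flat"]) == []

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            covariate_select(self._clin(0), [])


class TestFitLinear:
    def test_perfect_line(self):
        d = pd.DataFrame({"age": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]})
        res = fit_linear(d, "y")
        assert res.coefficient == pytest.approx(1.0)
        assert res.n_used == 3

    def test_null_pvalues_uniform(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            d = pd.DataFrame(
                {"age": rng.uniform(30, 85, 200), "y": rng.normal(size=200)}
            )
            hits += fit_linear(d, "y").p < 0.05
        assert 0.02 < hits / reps < 0.08

    def test_planted_slope_ci_coverage(self, rng):
        covered = 0
        reps = 200
        for _ in range(reps):
            age = rng.uniform(30, 85, 150)
            y = 0.2 * age + rng.normal(0, 2.0, 150)
            res = fit_linear(pd.DataFrame({"age": age, "y": y}), "y")
            covered += res.ci_low <= 0.2 <= res.ci_high
        assert covered / reps > 0.90

    def test_rank_deficient_design_names_aliased_column(self, rng):
        n = 50
        d = pd.DataFrame(
            {
                "age": rng.uniform(30, 85, n),
                "y": rng.normal(size=n),
            }
        )
        d["twin"] = d["age"] * 2.0
        with pytest.raises(np.linalg.LinAlgError, match="twin"):
            fit_linear(d, "y", covariates=["twin"])

    def test_categorical_covariate_dummy_expansion(self, rng):
        n = 120
        d = pd.DataFrame(
            {
                "age": rng.uniform(30, 85, n),
                "stage": rng.choice(["I", "II", "III"], n),
            }
        )
        d["y"] = 0.1 * d["age"] + (d["stage"] == "III") * 3 + rng.normal(0, 1, n)
        res = fit_linear(d, "y", covariates=["stage"])
        assert res.ci_low <= 0.1 <= res.ci_high


class TestFitLogistic:
    def test_2x2_closed_form_odds_ratio(self):
        a, b, c, d = 20, 10, 15, 30
        df = pd.DataFrame(
            {
                "age": [1.0] * (a + b) + [0.0] * (c + d),
                "y": [1] * a + [0] * b + [1] * c + [0] * d,
            }
        )
        res = fit_logistic(df, "y")
        assert res.or_per_year == pytest.approx((a * d) / (b * c), rel=1e-5)

    def test_separated_data_raises(self):
        df = pd.DataFrame({"age": np.arange(10.0), "y": (np.arange(10) >= 5).astype(int)})
        with pytest.raises(SeparationError):
            fit_logistic(df, "y")
        res = fit_firth(df, "y")
        assert np.isfinite(res.coefficient)

    def test_one_class_outcome_errors(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0], "y": [1, 1, 1]})
        with pytest.raises(ValueError, match="single-class"):
            fit_logistic(df, "y")

    def test_null_or_near_one(self, rng):
        n = 2000
        df = pd.DataFrame(
            {"age": rng.uniform(30, 85, n), "y": (rng.random(n) < 0.5).astype(int)}
        )
        res = fit_logistic(df, "y")
        assert res.or_ci_low <= 1.0 <= res.or_ci_high

    def test_wald_ci_coverage_for_planted_or(self, rng):
        covered = 0
        reps = 150
        for _ in range(reps):
            n = 800
            age = rng.uniform(30, 85, n)
            p = 1 / (1 + np.exp(-(-1.7 + np.log(1.03) * age)))
            y = (rng.random(n) < p).astype(int)
            res = fit_logistic(pd.DataFrame({"age": age, "y": y}), "y")
            covered += res.or_ci_low <= 1.03 <= res.or_ci_high
        assert 0.90 <= covered / reps <= 1.0


def _cohort_frame(rng, n, label, slope=0.0, sigma=1.0):
    age = rng.uniform(30, 85, n)
    return pd.DataFrame(
        {
            "sample_id": [f"{label}{i}" for i in range(n)],
            "age": age,
            "cancer_type": label,
            "y": slope * age + rng.normal(0, sigma, n),
        }
    )


class TestCascade:
    def test_planted_cohort_reaches_stage_two(self, rng):
        frames = [_cohort_frame(rng, 150, f"C{i}") for i in range(5)]
        frames.append(_cohort_frame(rng, 150, "HIT", slope=0.05, sigma=0.5))
        data = pd.concat(frames, ignore_index=True)
        results = AgeAssociationCascade(data, "y", covariate_candidates=[]).fit()
        assert results.screened_in == ["HIT"]
        adjusted = [r for r in results.adjusted_results]
        assert len(adjusted) == 1 and adjusted[0].cohort == "HIT"
        assert adjusted[0].stage == "adjusted"

    def test_no_stage_two_rows_for_screened_out_cohorts(self, rng):
        data = pd.concat(
            [_cohort_frame(rng, 100, f"C{i}") for i in range(4)], ignore_index=True
        )
        results = AgeAssociationCascade(data, "y", covariate_candidates=[]).fit()
        stage2_cohorts = {r.cohort for r in results.adjusted_results}
        assert stage2_cohorts <= set(results.screened_in)

    def test_binary_outcome_routes_through_firth_on_separation(self, rng):
        n = 40
        age = np.sort(rng.uniform(30, 85, n))
        data = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "age": age,
                "cancer_type": "A",
                "y": (age > np.median(age)).astype(int),
            }
        )
        results = AgeAssociationCascade(data, "y", kind="binary",
                                        covariate_candidates=[]).fit()
        assert results.screen_results[0].method == "firth"
        assert np.isfinite(results.screen_results[0].or_per_year)

    def test_purity_enters_stage_two(self, rng):
        f = _cohort_frame(rng, 200, "HIT", slope=0.05, sigma=0.5)
        f["purity"] = rng.beta(5, 2, len(f))
        results = AgeAssociationCascade(f, "y", covariate_candidates=[]).fit()
        assert "purity" in results.adjusted_results[0].covariates

    def test_summary_text(self, rng):
        data = _cohort_frame(rng, 80, "A")
        res = AgeAssociationCascade(data, "y", covariate_candidates=[]).fit()
        assert "cohorts screened" in res.summary()

    def test_pan_cancer_includes_cancer_type(self, rng):
        frames = [_cohort_frame(rng, 80, f"C{i}", slope=0.02) for i in range(3)]
        data = pd.concat(frames, ignore_index=True)
        data["gender"] = rng.choice(["f", "m"], len(data))
        res = AgeAssociationCascade(data, "y").fit_pan_cancer()
        assert res.cohort == "pan-cancer"
        assert any(c in ("cancer_type",) for c in res.covariates)


class TestRankGroupTests:
    def test_worked_kruskal_example(self):
        out = rank_group_tests([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert out.kruskal_h == pytest.approx(27 / 7)  # 3.857
        assert out.p_source == "exact"
        assert out.kruskal_p == pytest.approx(0.1)  # 2 of 20 assignments
        assert out.wilcoxon_p is not None

    def test_identical_constant_groups(self):
        out = rank_group_tests([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert out.kruskal_h == 0.0 and out.kruskal_p == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rank_group_tests([1.0, 2.0], ["a", "a"])

    def test_dunn_z_hand_computation(self):
        # no ties: sigma = N(N+1)/12 = 3.5; z = (2 - 5)/sqrt(3.5 * 2/3)
        out = rank_group_tests(
            [1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3, exact_max_n=0
        )
        z = out.dunn.iloc[0]["z"]
        assert abs(z) == pytest.approx(3 / np.sqrt(3.5 * (2 / 3)))

    def test_dunn_bonferroni_multiplies_pairs(self, rng):
        vals = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        out = rank_group_tests(vals, labels)
        assert len(out.dunn) == 3
        assert np.all(
            out.dunn["adj_p"] >= out.dunn["p"] - 1e-12
        )

    def test_exact_p_matches_monte_carlo_permutations(self, rng):
        for _ in range(8):
            n = int(rng.integers(5, 9))
            k = 2 if n < 7 else int(rng.integers(2, 4))
            labels = rng.permutation(
                np.concatenate([[f"g{i}"] * 2 for i in range(k)]
                               + [[f"g{rng.integers(k)}"] * (n - 2 * k)])
            )
            vals = np.round(rng.normal(size=n), 1)
            out = rank_group_tests(vals, labels)
            assert out.p_source in ("exact", "degenerate")
            if out.p_source != "exact":
                continue
            # Monte-Carlo oracle: permute labels, recompute H via scipy
            from scipy import stats as sps

            groups = lambda lab: [vals[lab == g] for g in np.unique(labels)]
            try:
                h_obs = sps.kruskal(*groups(labels)).statistic
            except ValueError:
                continue
            B = 3000
            count = 0
            for _ in range(B):
                perm = rng.permutation(labels)
                h = sps.kruskal(*groups(perm)).statistic
                count += h >= h_obs - 1e-12
            mc_p = count / B
            se = np.sqrt(mc_p * (1 - mc_p) / B) + 1e-9
            assert abs(out.kruskal_p - mc_p) < max(4 * se, 0.02)
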
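import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncoage.containers import OmicsMatrix
from oncoage.exprmeth import (
    classify_overlap,
    coefficient_concordance,
    correlation_groups,
    age_feature_regression,
    filter_expressed,
    gene_meth_expr_correlation,
    log2_expr,
    make_ranked_list,
    map_probes,
)
from oncoage.simulate import SimulationParams, simulate_clinical, simulate_expr_meth


def _expr(values, genes=None, samples=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    samples = samples or [f"S{i}" for i in range(len(values[0]))]
    return OmicsMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), kind="expression"
    )


class TestExpressionFilter:
    def test_kept_at_51_of_100(self):
        vals = [[1.0] * 51 + [0.0] * 49]
        assert len(filter_expressed(_expr(vals)).features) == 1

    def test_dropped_at_50_of_100(self):
        vals = [[1.0] * 50 + [0.0] * 50]
        assert len(filter_expressed(_expr(vals)).features) == 0

    def test_all_zero_gene_dropped(self):
        vals = [[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]]
        out = filter_expressed(_expr(vals))
        assert list(out.features) == ["G1"]


class TestLog2:
    @pytest.mark.parametrize("raw, expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_offset_transform(self, raw, expected):
        out = log2_expr(_expr([[raw]]))
        assert out.values.iloc[0, 0] == expected
        assert out.log_transformed


def _probe_matrix(rows, probes, samples=None):
    samples = samples or [f"S{i}" for i in range(len(rows[0]))]
    return OmicsMatrix(
        values=pd.DataFrame(rows, index=probes, columns=samples), kind="methylation"
    )


class TestMapProbes:
    def _setup(self):
        e = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = OmicsMatrix(
            values=pd.DataFrame([e], index=["G1"], columns=[f"S{i}" for i in range(5)]),
            kind="expression",
            log_transformed=True,
        )
        return e, expr

    def test_most_negative_probe_selected(self):
        e, expr = self._setup()
        anti = 1.0 - e / 10.0  # r = -1
        weak = np.array([0.5, 0.4, 0.55, 0.45, 0.5])
        meth = _probe_matrix([weak, anti], ["p_weak", "p_anti"])
        pm = pd.DataFrame({"probe": ["p_weak", "p_anti"], "gene": ["G1", "G1"]})
        gm, mapping = map_probes(meth, pm, expr)
        assert mapping.loc[0, "probe"] == "p_anti"
        assert mapping.loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_single_probe_selected_unconditionally(self):
        e, expr = self._setup()
        meth = _probe_matrix([e / 10.0], ["p_only"])  # positively correlated
        pm = pd.DataFrame({"probe": ["p_only"], "gene": ["G1"]})
        _, mapping = map_probes(meth, pm, expr)
        assert mapping.loc[0, "probe"] == "p_only"

    def test_exact_tie_breaks_lexicographically_and_order_invariant(self):
        e, expr = self._setup()
        anti = 1.0 - e / 10.0
        pm = pd.DataFrame({"probe": ["pB", "pA"], "gene": ["G1", "G1"]})
        for probe_order in (["pB", "pA"], ["pA", "pB"]):
            meth = _probe_matrix([anti, anti], probe_order)
            _, mapping = map_probes(meth, pm, expr)
            assert mapping.loc[0, "probe"] == "pA"

    def test_no_shared_samples_errors(self):
        _, expr = self._setup()
        meth = _probe_matrix([[0.5, 0.5, 0.4]], ["p1"], samples=["X1", "X2", "X3"])
        pm = pd.DataFrame({"probe": ["p1"], "gene": ["G1"]})
        with pytest.raises(ValueError, match="shared samples"):
            map_probes(meth, pm, expr)


def _clinical(n, rng):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "age": rng.integers(30, 86, n),
        }
    )


class TestAgeFeatureRegression:
    def test_matches_correlation_t_test_without_covariates(self, rng):
        n = 60
        clin = _clinical(n, rng)
        vals = rng.normal(size=(5, n))
        m = OmicsMatrix(
            values=pd.DataFrame(
                vals, index=[f"G{i}" for i in range(5)], columns=clin["sample_id"]
            ),
            kind="expression",
            log_transformed=True,
        )
        res = age_feature_regression(m, clin)
        for i in range(5):
            r, p = stats.pearsonr(clin["age"], vals[i])
            assert res.loc[f"G{i}", "p"] == pytest.approx(p, abs=1e-10)

    def test_constant_feature_skipped(self, rng):
        clin = _clinical(30, rng)
        vals = np.vstack([np.full(30, 2.0), rng.normal(size=30)])
        m = OmicsMatrix(
            values=pd.DataFrame(vals, index=["flat", "ok"], columns=clin["sample_id"]),
            kind="expression",
            log_transformed=True,
        )
        res = age_feature_regression(m, clin)
        assert "flat" not in res.index and "ok" in res.index

    def test_missing_values_complete_case_per_feature(self, rng):
        n = 50
        clin = _clinical(n, rng)
        y = 0.01 * clin["age"].to_numpy() + rng.normal(0, 0.01, n)
        y[:5] = np.nan
        m = OmicsMatrix(
            values=pd.DataFrame([y], index=["G0"], columns=clin["sample_id"]),
            kind="expression",
            log_transformed=True,
        )
        res = age_feature_regression(m, clin)
        assert res.loc["G0", "coefficient"] == pytest.approx(0.01, abs=0.005)

    def test_planted_signal_flagged(self, rng):
        n = 300
        clin = _clinical(n, rng)
        age = clin["age"].to_numpy(float)
        planted = 0.3 + 0.005 * age + rng.normal(0, 0.05, (5, n))
        noise = 0.4 + rng.normal(0, 0.05, (45, n))
        m = OmicsMatrix(
            values=pd.DataFrame(
                np.clip(np.vstack([planted, noise]), 0, 1),
                index=[f"A{i}" for i in range(5)] + [f"N{i}" for i in range(45)],
                columns=clin["sample_id"],
            ),
            kind="methylation",
        )
        res = age_feature_regression(m, clin)
        assert res.loc[[f"A{i}" for i in range(5)], "flag"].all()
        assert res["direction"].loc["A0"] == "up"


class TestOverlapClassification:
    def _results(self, spec):
        """spec: {gene: (flag, direction, coefficient)}"""
        df = pd.DataFrame(
            [(g, f, d, c) for g, (f, d, c) in spec.items()],
            columns=["feature", "flag", "direction", "coefficient"],
        ).set_index("feature")
        df["adj_p"] = np.where(df["flag"], 0.01, 0.5)
        return df

    def test_ovarian_like_counts_give_84_percent(self):
        expr = {}
        meth = {}
        for i in range(44):
            g = f"G{i}"
            expr[g] = (True, "down" if i < 37 else "up", -1.0 if i < 37 else 1.0)
            meth[g] = (True, "up", 1.0)
        out = classify_overlap(self._results(expr), self._results(meth))
        assert out.n_overlap == 44
        assert round(out.opposite_pct) == 84

    def test_up_up_quadrant(self):
        expr = {"G": (True, "up", 1.0)}
        meth = {"G": (True, "up", 1.0)}
        out = classify_overlap(self._results(expr), self._results(meth))
        assert out.quadrants["G"] == "meth_up_expr_up"

    def test_empty_overlap_percentage_undefined(self):
        expr = {"A": (True, "up", 1.0)}
        meth = {"B": (True, "up", 1.0)}
        out = classify_overlap(self._results(expr), self._results(meth))
        assert out.n_overlap == 0 and np.isnan(out.opposite_pct)
        assert set(out.groups.unique()) == {"age-DEGs", "age-DMGs"}

    def test_quadrant_counts_sum_to_overlap(self, rng):
        expr, meth = {}, {}
        for i in range(30):
            g = f"G{i}"
            expr[g] = (bool(rng.random() < 0.5), rng.choice(["up", "down"]), 0.1)
            meth[g] = (bool(rng.random() < 0.5), rng.choice(["up", "down"]), 0.1)
        out = classify_overlap(self._results(expr), self._results(meth))
        assert sum(out.quadrant_counts.values()) == out.n_overlap
        assert (out.groups == "age-DMGs-DEGs").sum() == out.n_overlap


class TestConcordanceAndRanking:
    def _res(self, coefs):
        df = pd.DataFrame(
            {"feature": list(coefs), "coefficient": list(coefs.values())}
        ).set_index("feature")
        df["p"] = 0.5
        df["adj_p"] = 0.5
        df["flag"] = False
        df["direction"] = np.where(df["coefficient"] >= 0, "up", "down")
        return df

    def test_exact_negative_proportionality(self):
        e = self._res({"A": 0.1, "B": -0.2, "C": 0.3})
        m = self._res({"A": -0.2, "B": 0.4, "C": -0.6})
        r, _ = coefficient_concordance(e, m)
        assert r == pytest.approx(-1.0)

    def test_independent_coefficients_near_zero(self, rng):
        n = 2000
        e = self._res({f"G{i}": float(x) for i, x in enumerate(rng.normal(size=n))})
        m = self._res({f"G{i}": float(x) for i, x in enumerate(rng.normal(size=n))})
        r, _ = coefficient_concordance(e, m)
        assert abs(r) < 3 / np.sqrt(n)

    def test_ranked_list_order(self):
        res = self._res({"A": 0.2, "B": -0.1, "C": 0.5})
        out = make_ranked_list(res)
        assert out["feature"].tolist() == ["C", "A", "B"]

    def test_ranked_list_ties_lexicographic(self):
        res = self._res({"B": 0.1, "A": 0.1, "C": 0.1})
        assert make_ranked_list(res)["feature"].tolist() == ["A", "B", "C"]

    def test_empty_results_error(self):
        with pytest.raises(ValueError):
            make_ranked_list(self._res({}))


class TestPlantedCouplingPipeline:
    def _run_once(self, seed, coupling=-4.0):
        params = SimulationParams(
            n_samples=150,
            seed=seed,
            n_genes=120,
            n_age_genes=15,
            coupling=coupling,
        )
        rng = np.random.default_rng(seed)
        clin = simulate_clinical(params, rng)
        expr, meth, pm, truth = simulate_expr_meth(clin, params, rng)
        lexpr = log2_expr(expr)
        gene_meth, mapping = map_probes(meth, pm, lexpr)
        expr_res = age_feature_regression(lexpr, clin)
        meth_res = age_feature_regression(gene_meth, clin)
        return clin, lexpr, gene_meth, expr_res, meth_res, truth, mapping

    def test_coupled_group_has_most_negative_correlation(self):
        worse = 0
        for seed in range(20):
            _, lexpr, gm, er, mr, truth, _ = self._run_once(seed)
            table, tests = correlation_groups(lexpr, gm, er, mr)
            med = table.groupby("group")["pearson_r"].mean()
            if "age-DMGs-DEGs" in med.index and "others" in med.index:
                worse += med["age-DMGs-DEGs"] < med["others"]
        assert worse == 20

    def test_planted_genes_fall_in_meth_up_expr_down_quadrant(self):
        _, _, _, er, mr, truth, _ = self._run_once(3)
        out = classify_overlap(er, mr)
        planted = set(truth.loc[truth["is_age_gene"], "gene"])
        overlap_planted = [g for g in out.quadrants.index if g in planted]
        assert len(overlap_planted) > 0
        frac = np.mean(
            [out.quadrants[g] == "meth_up_expr_down" for g in overlap_planted]
        )
        assert frac >= 0.9

    def test_concordance_negative_under_negative_coupling(self):
        for seed in range(5):
            _, _, _, er, mr, _, _ = self._run_once(seed)
            r, _ = coefficient_concordance(er, mr)
            assert r < 0

    def test_gene_meth_expr_correlation_bounds(self):
        _, lexpr, gm, _, _, _, _ = self._run_once(0)
        r = gene_meth_expr_correlation(lexpr, gm)
        assert r.between(-1, 1).all()
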
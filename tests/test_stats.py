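"""Statistics layer: consolidation, summaries, tests, PCA, reproducibility."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sama3d.stats import (
    compare_groups,
    consolidate,
    exact_rank_sum_p,
    generate_report,
    reproducibility_curves,
    run_pca,
    summarize,
    wilcoxon_rank_sum,
)


def _tables(n_stacks=4, n_rows=5, seed=0):
    rng = np.random.default_rng(seed)
    tables = {}
    for i in range(n_stacks):
        tables[f"s{i}"] = pd.DataFrame({
            "label": np.arange(1, n_rows + 1),
            "volume": rng.uniform(100, 200, n_rows),
            "elon1": rng.uniform(1, 3, n_rows),
            "elon2": rng.uniform(1, 2, n_rows),
            "rlv": rng.uniform(0, 0.3, n_rows),
            "n_lumena": rng.integers(0, 3, n_rows),
            "n_branches": rng.integers(1, 4, n_rows),
        })
    meta = pd.DataFrame({
        "stack": [f"s{i}" for i in range(n_stacks)],
        "condition": ["A" if i < n_stacks // 2 else "B" for i in range(n_stacks)],
        "replicate": [i % 2 for i in range(n_stacks)],
    })
    return tables, meta


class TestConsolidate:
    def test_row_count_and_annotation(self):
        tables, meta = _tables()
        study = consolidate(tables, meta)
        assert len(study) == 20
        assert set(study.columns) >= {"stack", "condition", "replicate", "volume"}

    def test_missing_metadata_is_error(self):
        tables, meta = _tables()
        with pytest.raises(ValueError, match="s3"):
            consolidate(tables, meta[meta["stack"] != "s3"])

    def test_duplicate_rows_rejected(self):
        tables, meta = _tables()
        tables["s0"] = pd.concat([tables["s0"], tables["s0"].iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            consolidate(tables, meta)

    def test_exclusion_toggles_drop_columns(self):
        tables, meta = _tables()
        no_lumen = consolidate(tables, meta, include_lumen=False)
        assert "rlv" not in no_lumen.columns and "n_lumena" not in no_lumen.columns
        no_branch = consolidate(tables, meta, include_branching=False)
        assert "n_branches" not in no_branch.columns

    def test_missing_lumen_defaults_to_zero(self):
        tables, meta = _tables()
        for t in tables.values():
            t.drop(columns=["n_lumena"], inplace=True)
        study = consolidate(tables, meta)
        assert (study.n_lumena == 0).all()


class TestSummarize:
    def test_hand_computed_values(self):
        table = pd.DataFrame({
            "condition": "A", "replicate": 1, "x": [1.0, 2.0, 3.0, 4.0],
        })
        row = summarize(table, "x").iloc[0]
        assert row["mean"] == pytest.approx(2.5)
        assert row["median"] == pytest.approx(2.5)
        assert row["sd"] == pytest.approx(1.2909944, rel=1e-6)
        assert row["cv"] == pytest.approx(0.51639778, rel=1e-6)

    def test_constant_column(self):
        table = pd.DataFrame({"condition": "A", "replicate": 1, "x": [5.0] * 4})
        row = summarize(table, "x").iloc[0]
        assert row["sd"] == 0 and row["cv"] == 0 and row["median"] == row["mean"]

    def test_zero_mean_cv_missing(self):
        table = pd.DataFrame({"condition": "A", "replicate": 1, "x": [-1.0, 1.0]})
        assert np.isnan(summarize(table, "x").iloc[0]["cv"])

    def test_unknown_parameter(self):
        with pytest.raises(KeyError):
            summarize(pd.DataFrame({"condition": [], "replicate": []}), "nope")


def brute_force_rank_sum_p(x, y):
    """Oracle: enumerate every C(n+m, n) group labeling explicitly."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    mu = n * ranks.mean()
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 8, size=2)
        # integer draws so ties occur
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, m).astype(float)
        assert exact_rank_sum_p(x, y) == pytest.approx(brute_force_rank_sum_p(x, y))

    def test_complete_separation_six_vs_six(self):
        x, y = np.arange(6, dtype=float), np.arange(10, 16, dtype=float)
        assert exact_rank_sum_p(x, y) == pytest.approx(2 / 924)

    def test_identical_groups_p_one(self):
        x = np.array([1.0, 1.0, 1.0])
        assert exact_rank_sum_p(x, x) == 1.0

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        ours = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(float(ref))


class TestCompareGroups:
    def _study(self, a_vals, b_vals):
        rows = []
        for i, v in enumerate(a_vals):
            rows.append({"condition": "A", "stack": f"a{i}", "x": v})
        for i, v in enumerate(b_vals):
            rows.append({"condition": "B", "stack": f"b{i}", "x": v})
        return pd.DataFrame(rows)

    def test_reported_p_is_maximum(self):
        res = compare_groups(self._study([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12]), "x")
        assert res.wilcoxon_p == pytest.approx(2 / 924)
        assert res.reported_p == max(res.anova_p, res.wilcoxon_p)
        assert res.reported_p >= res.anova_p and res.reported_p >= res.wilcoxon_p

    def test_anova_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        res = compare_groups(self._study(a, b), "x")
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert res.anova_p == pytest.approx(float(t_p), abs=1e-10)

    def test_identical_groups(self):
        res = compare_groups(self._study([2.0] * 4, [2.0] * 4), "x")
        assert res.wilcoxon_p == 1.0 and res.reported_p == 1.0

    def test_three_groups_skip_wilcoxon(self):
        df = self._study([1, 2, 3], [4, 5, 6])
        extra = pd.DataFrame(
            {"condition": "C", "stack": ["c0", "c1", "c2"], "x": [7.0, 8.0, 9.0]}
        )
        res = compare_groups(pd.concat([df, extra]), "x")
        assert res.wilcoxon_p is None and res.reported_p == res.anova_p

    def test_undersized_group_is_error(self):
        with pytest.raises(ValueError, match="'B'"):
            compare_groups(self._study([1, 2, 3], [4]), "x")

    def test_structure_unit_pools_rows(self):
        df = self._study([1, 2, 3], [4, 5, 6])
        df = pd.concat([df, df.assign(x=df.x + 0.1)])  # two structures per stack
        res = compare_groups(df, "x", unit="structure")
        assert res.n_per_group == [6, 6]


class TestPCA:
    def test_perfectly_correlated_pair_is_rank_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        table = pd.DataFrame({"u": a, "v": 3 * a + 1})
        res = run_pca(table, ["u", "v"])
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal_and_scores_centered(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        res = run_pca(table, list("abcd"))
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-8)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_of_correlation_matrix(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5)) @ rng.normal(size=(5, 5))
        table = pd.DataFrame(X, columns=list("abcde"))
        res = run_pca(table, list("abcde"))
        corr = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(res.explained_variance_ratio, evals / evals.sum(), atol=1e-8)
        for k in range(5):  # eigenvectors defined up to sign
            dot = abs(evecs[:, k] @ res.loadings[:, k])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30),
                              "c": 1.0})
        res = run_pca(table, ["a", "b", "c"])
        assert res.variables == ["a", "b"]


class TestReproducibility:
    def _table(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 200)
        b = a.copy() if shift == 0 else rng.normal(shift, 1, 200)
        return pd.DataFrame({
            "condition": "A",
            "replicate": ["r1"] * 200 + ["r2"] * 200,
            "x": np.concatenate([a, b]),
        })

    def test_identical_replicates_superimpose(self):
        res = reproducibility_curves(self._table(0.0), "x", "A")
        d1, d2 = res.densities["r1"], res.densities["r2"]
        assert np.allclose(d1, d2)
        assert res.ks_distance.loc["r1", "r2"] == 0.0

    def test_densities_normalized(self):
        res = reproducibility_curves(self._table(0.5), "x", "A")
        dx = res.grid[1] - res.grid[0]
        for dens in res.densities.values():
            assert dens.sum() * dx == pytest.approx(1.0, abs=0.01)

    def test_shifted_replicate_detected(self):
        res = reproducibility_curves(self._table(2.0, seed=5), "x", "A")
        assert res.ks_distance.loc["r1", "r2"] > 0.5

    def test_unknown_condition(self):
        with pytest.raises(ValueError, match="condition"):
            reproducibility_curves(self._table(), "x", "Z")


def test_benjamini_hochberg_matches_reference():
    from statsmodels.stats.multitest import multipletests
    from sama3d.stats import benjamini_hochberg

    rng = np.random.default_rng(8)
    p = rng.uniform(0, 1, 15)
    ours = benjamini_hochberg(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(ours, ref)


class TestReport:
    def test_report_complete_and_deterministic(self, tmp_path):
        tables, meta = _tables(n_stacks=4, n_rows=30, seed=4)
        study = consolidate(tables, meta)
        params = ["volume", "elon1", "rlv"]
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        idx = generate_report(study, out1, parameters=params)
        generate_report(study, out2, parameters=params)
        for p in params:
            assert (out1 / f"{p}.png").exists()
        tests = pd.read_csv(out1 / "tests.csv")
        assert set(tests.parameter) == set(params)
        # two conditions: both p-values present, max rule holds
        assert tests.wilcoxon_p.notna().all()
        assert (tests.reported_p >= tests.anova_p - 1e-12).all()
        assert (out1 / "summary.csv").read_bytes() == (out2 / "summary.csv").read_bytes()
        assert (out1 / "tests.csv").read_bytes() == (out2 / "tests.csv").read_bytes()
        assert "pca.png" in idx["files"]
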
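import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lymphoslope.exosome import (
    CompositeScoreDef,
    CountMatrix,
    best_subset,
    composite_score,
    correlation_screen,
    filter_detected,
    paired_log2fc,
    tmm_factors,
    wilcoxon_ranksum,
)

from oracles import best_subsets_ols, ranksum_exact_enumeration, tmm_reference_recipe


def make_counts(mat, n_patients=None, genes=None):
    mat = np.asarray(mat)
    n_samples = mat.shape[1]
    assert n_samples % 2 == 0
    pids = [f"P{i}" for i in range(n_samples // 2)]
    names, sheet = [], []
    for pid in pids:
        for role, suffix in (("control", "C"), ("treatment", "T")):
            names.append(f"{pid}_{suffix}")
            sheet.append({"sample_id": f"{pid}_{suffix}", "patient_id": pid, "role": role})
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return CountMatrix(
        counts=pd.DataFrame(mat, index=genes, columns=names),
        samples=pd.DataFrame(sheet).set_index("sample_id"),
    )


class TestFilterDetected:
    def test_boundary_and_extremes(self):
        mat = np.array(
            [
                [0, 0, 0, 0],  # undetected everywhere -> removed
                [5, 3, 0, 0],  # exactly half -> retained
                [1, 0, 0, 0],  # a quarter -> removed
                [9, 9, 9, 9],  # everywhere -> retained
            ]
        )
        cm = make_counts(mat)
        out, removed = filter_detected(cm)
        assert list(out.counts.index) == ["g1", "g3"]
        assert removed == ["g0", "g2"]

    def test_idempotent(self, rng):
        cm = make_counts(rng.poisson(1.0, (30, 6)))
        once, _ = filter_detected(cm)
        twice, removed = filter_detected(once)
        assert removed == []
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        col = np.array([100, 50, 20, 400, 30, 10])
        cm = make_counts(np.column_stack([col] * 4))
        f = tmm_factors(cm)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_difference_unit_factors(self):
        """One library exactly 2x another has all M-values 0 after depth scaling."""
        col = np.array([100, 50, 20, 400, 30])
        cm = make_counts(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(cm), 1.0, atol=1e-12)

    def test_matches_step_by_step_recipe(self, rng):
        """Inflated-gene toy: vectorized implementation equals the loop-based
        published-recipe oracle to 1e-8."""
        mat = rng.poisson(80, (40, 6)).astype(float) + 1
        mat[0, 0] *= 40  # composition outlier in one library
        cm = make_counts(mat)
        ours = tmm_factors(cm).to_numpy()
        ref = np.array(tmm_reference_recipe(mat))
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_matches_edger(self, tmp_path, rng):
        """Cross-check against edgeR's calcNormFactors TMM on a small matrix."""
        mat = rng.poisson(60, (60, 4)).astype(int) + 1
        mat[:5, 1] *= 8
        cm = make_counts(mat)
        csv = tmp_path / "m.csv"
        pd.DataFrame(mat).to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(edgeR))
            m <- as.matrix(read.csv("{csv}"))
            f <- calcNormFactors(DGEList(counts=m), method="TMM")$samples$norm.factors
            cat(sprintf("%.12f", f), sep="\\n")
            """
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        assert out.returncode == 0, out.stderr
        edger = np.array([float(x) for x in out.stdout.split()])
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), edger, atol=1e-6)

    def test_properties(self, rng):
        cm = make_counts(rng.poisson(50, (50, 6)) + 1)
        f = tmm_factors(cm)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-10)
        scaled = make_counts(cm.counts.to_numpy() * 3)
        np.testing.assert_allclose(tmm_factors(scaled), f, atol=1e-12)

    def test_disjoint_support_errors(self):
        mat = np.array([[10, 0], [20, 0], [0, 5], [0, 9]])
        cm = make_counts(mat)
        with pytest.raises(ValueError, match="co-detected"):
            tmm_factors(cm)


class TestPairedLog2FC:
    def test_equal_normalized_counts_zero(self):
        col = np.array([100, 50, 20, 400])
        cm = make_counts(np.column_stack([col, col, col, col]))
        fc = paired_log2fc(cm)
        np.testing.assert_allclose(fc.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_gene_is_about_one(self, rng):
        base = rng.poisson(2000, 40) + 500
        trt = base.copy()
        # double one gene; library recomposition is negligible with many genes
        trt[0] *= 2
        others = rng.poisson(2000, (40, 2)) + 500
        cm = make_counts(np.column_stack([base, trt, others]))
        fc = paired_log2fc(cm, pseudocount=0.5)
        assert fc.iloc[0, 0] == pytest.approx(1.0, abs=0.05)

    def test_zero_zero_gene_is_zero(self):
        mat = np.array([[0, 0, 0, 0], [100, 120, 90, 100], [50, 40, 60, 55]])
        cm = make_counts(mat)
        fc = paired_log2fc(cm)
        np.testing.assert_allclose(fc.loc["g0"], 0.0, atol=1e-12)

    def test_antisymmetric_under_role_swap(self, rng):
        mat = rng.poisson(100, (20, 6)) + 1
        cm = make_counts(mat)
        swapped_sheet = cm.samples.copy()
        swapped_sheet["role"] = swapped_sheet["role"].map(
            {"control": "treatment", "treatment": "control"}
        )
        cm2 = CountMatrix(counts=cm.counts.copy(), samples=swapped_sheet)
        f = tmm_factors(cm)
        np.testing.assert_allclose(
            paired_log2fc(cm, f).to_numpy(), -paired_log2fc(cm2, f).to_numpy(), atol=1e-12
        )


class TestCorrelationScreen:
    def test_planted_alpha_gene_selected(self, rng):
        n = 30
        alpha = rng.normal(0.08, 0.03, n)
        strong = 10 * (alpha - alpha.mean()) + rng.normal(0, 0.1, n)
        fc = pd.DataFrame(
            {f"P{i}": [strong[i], rng.normal(), 1.0] for i in range(n)},
            index=["hit", "noise", "flat"],
        )
        pids = list(fc.columns)
        res = correlation_screen(
            fc,
            alpha=pd.Series(alpha, index=pids),
            nlr=pd.Series(rng.lognormal(1, 0.5, n), index=pids),
            dsd=pd.Series(rng.uniform(size=n) < 0.3, index=pids),
        )
        assert "hit" in res.selected
        assert "alpha" in res.table.loc["hit", "tag"]
        assert res.flagged == ["flat"]

    def test_nlr_alone_not_sufficient(self, rng):
        """A gene significant only against NLR (not death) must not be selected."""
        n = 40
        nlr = rng.lognormal(1, 0.5, n)
        gene = 3 * (nlr - nlr.mean()) + rng.normal(0, 0.05, n)
        fc = pd.DataFrame([gene, rng.normal(size=n)], index=["nlr_only", "noise"],
                          columns=[f"P{i}" for i in range(n)])
        res = correlation_screen(
            fc,
            alpha=pd.Series(rng.normal(0.08, 0.03, n), index=fc.columns),
            nlr=pd.Series(nlr, index=fc.columns),
            dsd=pd.Series(np.zeros(n, dtype=bool), index=fc.columns),
        )
        assert "nlr_only" not in res.selected


class TestBestSubset:
    def test_single_candidate(self, rng):
        fc = pd.DataFrame([rng.normal(size=10)], index=["g"], columns=[f"P{i}" for i in range(10)])
        y = pd.Series(rng.uniform(size=10) < 0.5, index=fc.columns).astype(float)
        res = best_subset(["g"], fc, y)
        assert res.selected_genes == ["g"]

    def test_matches_ols_enumeration_oracle(self, rng):
        from lymphoslope.simulate import simulate_subset_candidates

        fc, y = simulate_subset_candidates(30, rng=rng)
        res = best_subset(list(fc.index), fc, y, max_k=8)
        oracle = best_subsets_ols(list(fc.index), fc, y, max_k=8)
        for _, row in res.trace.iterrows():
            genes_o, r2_o, adj_o = oracle[row["k"]]
            assert set(row["genes"].split("|")) == set(genes_o)
            assert row["r2"] == pytest.approx(r2_o, abs=1e-10)
            assert row["adj_r2"] == pytest.approx(adj_o, abs=1e-10)

    def test_r2_trace_nondecreasing(self, rng):
        from lymphoslope.simulate import simulate_subset_candidates

        fc, y = simulate_subset_candidates(25, rng=rng)
        res = best_subset(list(fc.index), fc, y, max_k=6)
        assert np.all(np.diff(res.trace["r2"]) >= -1e-12)

    def test_budget_guard(self, rng):
        fc = pd.DataFrame(rng.normal(size=(30, 40)),
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"P{i}" for i in range(40)])
        y = pd.Series(rng.uniform(size=40) < 0.5, index=fc.columns).astype(float)
        with pytest.raises(ValueError, match="budget"):
            best_subset(list(fc.index), fc, y, max_k=15, budget=100)


class TestCompositeScore:
    def test_empty_definition_zero(self, rng):
        fc = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"),
                          columns=[f"P{i}" for i in range(4)])
        s = composite_score(fc, CompositeScoreDef())
        assert (s == 0).all()

    def test_signed_sum(self):
        fc = pd.DataFrame({"P0": [0.7, 0.3]}, index=["A", "B"])
        s = composite_score(fc, CompositeScoreDef(frozenset({"A"}), frozenset({"B"})))
        assert s["P0"] == pytest.approx(0.4)

    def test_missing_gene_errors(self):
        fc = pd.DataFrame({"P0": [0.7]}, index=["A"])
        with pytest.raises(KeyError):
            composite_score(fc, CompositeScoreDef(frozenset({"Z"})))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            CompositeScoreDef(frozenset({"A"}), frozenset({"A"}))

    @given(st.floats(-2, 2), st.floats(-2, 2))
    @settings(max_examples=20, deadline=None)
    def test_linear_in_fc(self, a, b):
        fc = pd.DataFrame({"P0": [a, b]}, index=["A", "B"])
        d = CompositeScoreDef(frozenset({"A"}), frozenset({"B"}))
        assert composite_score(2 * fc, d)["P0"] == pytest.approx(
            2 * composite_score(fc, d)["P0"], abs=1e-12
        )


class TestWilcoxonRankSum:
    def test_identical_samples_p_near_one(self):
        _, p = wilcoxon_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_fully_separated_exact_p(self):
        """x={1,2,3} vs y={4,5,6}: 2 of 20 orderings as extreme, p = 0.1."""
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_matches_exhaustive_enumeration_5v5(self, rng):
        for _ in range(5):
            vals = rng.permutation(np.arange(10, dtype=float) + rng.uniform(0, 0.5, 10))
            x, y = vals[:5], vals[5:]
            u_ours, p_ours = wilcoxon_ranksum(x, y)
            u_oracle, p_oracle = ranksum_exact_enumeration(x, y)
            assert u_ours == u_oracle
            assert p_ours == pytest.approx(p_oracle, abs=1e-12)
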
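"""Statistical operations against independent brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import dbk
from dbk import genesets
from dbk.io import BulkCounts
from dbk.stats import (
    cell_cycle_phase,
    chi_square_2x2,
    composition_from_counts,
    composition_table,
    deconvolve,
    filter_de_table,
    getmm,
    stress_score_by_type,
    wilcoxon_de,
)

from conftest import make_adata


# ---------------------------------------------------------------------------
# Oracles


def exact_rank_sum_p(x, y):
    """Two-sided exact permutation p for the rank-sum statistic.

    Enumerates all C(n1+n2, n1) group assignments of the pooled average
    ranks and counts deviations of the rank sum from its mean at least as
    large as observed.
    """
    pooled = list(x) + list(y)
    n = len(pooled)
    n1 = len(x)
    # average ranks by counting
    ranks = []
    for v in pooled:
        less = sum(1 for w in pooled if w < v)
        equal = sum(1 for w in pooled if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    mean_sum = n1 * (n + 1) / 2.0
    obs = abs(sum(ranks[:n1]) - mean_sum)
    count = 0
    total = 0
    for comb in combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in comb) - mean_sum) >= obs - 1e-12:
            count += 1
    return count / total


def tmm_factor_oracle(rpk, ref_col, obs_col, trim_m=0.3, trim_a=0.05):
    """Literal step-by-step trimmed weighted mean of M-values.

    Straight-line reimplementation: compute M, A and weights gene by gene,
    trim by sorting, average with inverse-variance weights.
    """
    obs = rpk[:, obs_col].astype(float)
    ref = rpk[:, ref_col].astype(float)
    n_obs, n_ref = obs.sum(), ref.sum()
    m_vals, a_vals, w_vals = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m_vals.append(np.log2((o / n_obs) / (r / n_ref)))
            a_vals.append(0.5 * np.log2((o / n_obs) * (r / n_ref)))
            w_vals.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    n = len(m_vals)
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    m_sorted = sorted(range(n), key=lambda i: m_vals[i])
    a_sorted = sorted(range(n), key=lambda i: a_vals[i])
    m_rank = {i: k + 1 for k, i in enumerate(m_sorted)}
    a_rank = {i: k + 1 for k, i in enumerate(a_sorted)}
    num = den = 0.0
    for i in range(n):
        if lo_m <= m_rank[i] <= hi_m and lo_a <= a_rank[i] <= hi_a:
            num += m_vals[i] / w_vals[i]
            den += 1.0 / w_vals[i]
    return 2.0 ** (num / den)


# ---------------------------------------------------------------------------
# Wilcoxon DE


class TestWilcoxonDE:
    def _adata(self, g1_vals, g2_vals, n_pad_genes=4):
        """One interesting gene plus flat padding genes."""
        n1, n2 = len(g1_vals), len(g2_vals)
        X = np.ones((n1 + n2, 1 + n_pad_genes))
        X[:n1, 0] = g1_vals
        X[n1:, 0] = g2_vals
        adata = make_adata(X)
        return adata, list(adata.obs_names[:n1]), list(adata.obs_names[n1:])

    def test_identical_groups_yield_nothing(self):
        adata, g1, g2 = self._adata([2, 2, 2, 2], [2, 2, 2, 2])
        out = wilcoxon_de(adata, g1, g2, logfc_min=0.0, min_pct=0.0)
        assert (out["logfc"] == 0).all() if len(out) else True
        assert len(out) == 0  # p = 1 for all-tied values

    def test_separated_toy_matches_exact_permutation(self):
        """{2,2,2,2,2} vs {0,0,0,0,0}: p equals the C(10,5)=252 enumeration."""
        adata, g1, g2 = self._adata([2] * 5, [0] * 5)
        out = wilcoxon_de(adata, g1, g2, logfc_min=0.5, min_pct=0.5, fdr=0.05)
        assert "g0" in list(out["gene"])
        p = out.loc[out["gene"] == "g0", "p"].iloc[0]
        exact = exact_rank_sum_p([2] * 5, [0] * 5)
        assert exact == pytest.approx(2 / 252, abs=1e-12)
        assert abs(p - exact) < 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_small_groups_match_exact_permutation(self, seed):
        """p within 0.01 of an independently coded exact permutation oracle
        for group sizes <= 8, including ties."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=rng.integers(4, 9)).astype(float)
        y = (rng.integers(0, 4, size=rng.integers(4, 9)) + rng.integers(0, 3)).astype(float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            y = y + 1
        adata, g1, g2 = self._adata(x, y)
        out = wilcoxon_de(adata, g1, g2, logfc_min=0.0, min_pct=0.0, fdr=1.1)
        p = out.loc[out["gene"] == "g0", "p"]
        if len(p) == 0:  # gene filtered out (flat) — nothing to compare
            return
        assert abs(p.iloc[0] - exact_rank_sum_p(x, y)) < 0.01

    def test_overlapping_groups_raise(self, norm_cells):
        cells = list(norm_cells.obs_names[:5])
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(norm_cells, cells, cells)

    def test_default_thresholds_match_printed_values(self):
        adata, g1, g2 = self._adata([2] * 5, [0] * 5)
        out = wilcoxon_de(adata, g1, g2)
        assert out.attrs["thresholds"] == {"logfc_min": 0.5, "min_pct": 0.5, "fdr": 0.05}

    def test_both_directions_reported(self):
        X = np.ones((10, 3))
        X[:5, 0] = 5.0  # up in group 1
        X[5:, 1] = 5.0  # up in group 2
        adata = make_adata(X)
        g1, g2 = list(adata.obs_names[:5]), list(adata.obs_names[5:])
        out = wilcoxon_de(adata, g1, g2, logfc_min=0.5, min_pct=0.5)
        assert set(out["direction"]) == {"up_group1", "up_group2"}


class TestFilterDETable:
    def test_printed_bulk_thresholds(self):
        table = pd.DataFrame(
            {"gene": ["a", "b", "c", "d"],
             "logfc": [2.5, -2.5, 1.0, 3.0],
             "q": [0.01, 0.01, 0.01, 0.2]}
        )
        out = filter_de_table(table, logfc_min=2.0, fdr=0.05)
        assert list(out["gene"]) == ["a", "b"]


# ---------------------------------------------------------------------------
# Stress score


class TestStressScore:
    def test_induced_type_flagged(self, truth):
        """8x stress induction flags only the induced type (power check)."""
        eff = dbk.ProtocolEffect(stress_multiplier={"Immune_like": 8.0})
        cells = dbk.simulate_cells(truth, 1500, [0.2] * 5, eff, depth_mean=5000, seed=31)
        norm = dbk.lognormalize(cells)
        table = stress_score_by_type(norm, norm.obs["true_type"], n_iter=999, seed=32)
        flagged = set(table.loc[table["significant"], "type"])
        assert flagged == {"Immune_like"}

    def test_stress_set_has_17_genes(self):
        assert len(genesets.STRESS_GENES) == 17

    def test_small_types_skipped(self, norm_cells):
        labels = norm_cells.obs["true_type"].astype(str).copy()
        labels.iloc[:2] = "rare"
        table = stress_score_by_type(norm_cells, labels, n_iter=99, seed=1)
        assert "rare" in table.attrs["skipped_types"]
        assert "rare" not in set(table["type"])


# ---------------------------------------------------------------------------
# Cell cycle


class TestCellCycle:
    def test_printed_gene_list_sizes(self):
        assert len(genesets.S_GENES) == 42
        assert len(genesets.G2M_GENES) == 52

    def test_phase_assignment_rules(self):
        """Cycling cells get their phase; non-cycling cells default to G1.

        Housekeeping genes matched in average expression to the cycle genes
        populate the control bins, so non-cycling cells score negative.
        """
        rng = np.random.default_rng(8)
        genes = (
            list(genesets.S_GENES[:10])
            + list(genesets.G2M_GENES[:10])
            + [f"hk{i}" for i in range(20)]
            + [f"bg{i}" for i in range(60)]
        )
        X = rng.poisson(2.0, size=(30, 100)).astype(float)
        X[:10, :10] += 15      # S-phase cells
        X[10:20, 10:20] += 15  # G2M cells
        X[:, 20:40] += 5       # housekeeping: high in every cell
        adata = make_adata(X, gene_names=genes)
        out = cell_cycle_phase(adata, seed=2, n_bins=5)
        assert (out["phase"][:10] == "S").all()
        assert (out["phase"][10:20] == "G2M").all()
        assert (out["phase"][20:] == "G1").mean() > 0.7

    def test_absent_lists_raise(self):
        adata = make_adata(np.ones((3, 4)))
        with pytest.raises(ValueError, match="cell-cycle"):
            cell_cycle_phase(adata)


# ---------------------------------------------------------------------------
# Composition


class TestComposition:
    def test_published_podocyte_counts(self):
        """330/11,851 cold vs 3/11,257 warm: 2.78% vs 0.03%, p < 0.001."""
        counts = pd.DataFrame(
            {"cold": [330, 11851 - 330], "warm": [3, 11257 - 3]},
            index=["podocyte", "other"],
        )
        result = composition_from_counts(counts, alpha=0.001)
        row = result.table.loc["podocyte"]
        assert round(row["pct_cold"], 2) == 2.78
        assert round(row["pct_warm"], 2) == 0.03
        assert row["p"] < 0.001
        assert bool(row["significant"])

    def test_equal_proportions_not_flagged(self):
        counts = pd.DataFrame({"a": [10, 90], "b": [10, 90]}, index=["t", "rest"])
        result = composition_from_counts(counts)
        assert result.table.loc["t", "chi2"] == 0.0
        assert result.table.loc["t", "p"] == 1.0
        assert not result.table.loc["t", "significant"]

    def test_statistic_matches_hand_formula(self):
        """Small 2x2 (4/10 vs 6/10) equals sum (O-E)^2 / E exactly."""
        obs = np.array([[4.0, 6.0], [6.0, 4.0]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        stat, _ = chi_square_2x2(4, 6, 6, 4)
        assert stat == pytest.approx(by_hand, abs=1e-12)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(list("ABCD"), 500)
        conditions = rng.choice(["x", "y"], 500)
        result = composition_table(labels, conditions)
        for cond in ("x", "y"):
            assert result.table[f"pct_{cond}"].sum() == pytest.approx(100.0, abs=0.01)

    def test_exclusion_set_recomputes_denominator(self):
        labels = ["PT"] * 50 + ["A"] * 30 + ["B"] * 20
        conditions = (["x"] * 25 + ["y"] * 25) + (["x"] * 20 + ["y"] * 10) + (
            ["x"] * 5 + ["y"] * 15
        )
        result = composition_table(labels, conditions, exclude_types=["PT"])
        assert "PT" not in result.table.index
        assert result.table["count_x"].sum() == 25
        assert result.table.loc["A", "pct_x"] == pytest.approx(100 * 20 / 25)

    def test_requires_two_conditions(self):
        with pytest.raises(ValueError, match="2 conditions"):
            composition_table(["A", "B"], ["x", "x"])


# ---------------------------------------------------------------------------
# GeTMM


class TestGeTMM:
    def _bulk(self, counts, lengths=None):
        genes = [f"g{i}" for i in range(counts.shape[0])]
        df = pd.DataFrame(
            counts, index=genes, columns=[f"s{j}" for j in range(counts.shape[1])]
        )
        if lengths is None:
            lengths = np.full(counts.shape[0], 1000)
        return BulkCounts(counts=df, lengths=pd.Series(lengths, index=genes))

    def test_identical_libraries_get_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, 30) + 1
        bulk = self._bulk(np.column_stack([col, col]))
        out = getmm(bulk)
        np.testing.assert_allclose(out.factors.to_numpy(), 1.0, atol=1e-12)
        pd.testing.assert_series_equal(out.normalized["s0"], out.normalized["s1"],
                                       check_names=False)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(50, 30) + 1
        bulk = self._bulk(np.column_stack([col, 2 * col]))
        out = getmm(bulk)
        np.testing.assert_allclose(out.factors.to_numpy(), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            out.normalized["s0"].to_numpy(), out.normalized["s1"].to_numpy(), rtol=1e-12
        )

    def test_factor_matches_literal_oracle(self):
        """20-gene two-sample toy with 4 shifted genes, independent oracle."""
        rng = np.random.default_rng(3)
        a = rng.poisson(100, 20) + 1
        b = rng.poisson(100, 20) + 1
        b[:4] *= 5
        lengths = rng.integers(500, 3000, 20)
        bulk = self._bulk(np.column_stack([a, b]), lengths)
        out = getmm(bulk)
        rpk = np.column_stack([a, b]) / (lengths[:, None] / 1000)
        ref = 0 if out.meta["reference_sample"] == "s0" else 1
        obs = 1 - ref
        raw = tmm_factor_oracle(rpk, ref, obs)
        # package factors are rescaled to geometric mean 1
        expected = np.array([1.0, raw]) if ref == 0 else np.array([raw, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(out.factors.to_numpy(), expected, atol=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(80, size=(50, 4)) + 1
        counts[:5, 1] *= 4
        out = getmm(self._bulk(counts))
        assert np.exp(np.mean(np.log(out.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_raises(self):
        counts = np.column_stack([np.arange(1, 11), np.zeros(10, dtype=int)])
        with pytest.raises(ValueError, match="all-zero"):
            getmm(self._bulk(counts))


# ---------------------------------------------------------------------------
# Deconvolution


@pytest.fixture(scope="module")
def three_type_setup():
    truth = dbk.generate_ground_truth(2000, 3, 10, seed=41)
    cells = dbk.simulate_cells(
        truth, 1500, [1 / 3, 1 / 3, 1 / 3], dbk.ProtocolEffect(), depth_mean=5000, seed=42
    )
    norm = dbk.lognormalize(cells)
    return truth, norm


class TestDeconvolve:
    def test_one_hot_bulk_recovered(self, three_type_setup):
        truth, norm = three_type_setup
        props = np.zeros(3)
        props[1] = 1.0
        bulk = dbk.simulate_bulk(truth, props, depth=1_000_000, seed=43)
        result = deconvolve(bulk, norm, norm.obs["true_type"])
        est = result.proportions.iloc[0]
        assert est[truth.type_names[1]] > 0.93
        assert est.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mixture_recovered_within_tolerance(self, three_type_setup):
        truth, norm = three_type_setup
        props = {"PT_like": 0.6, "aLOH_like": 0.3, "Endo_like": 0.1}
        vec = [props[t] for t in truth.type_names]
        bulk = dbk.simulate_bulk(truth, vec, depth=1_000_000, seed=44)
        result = deconvolve(bulk, norm, norm.obs["true_type"])
        for t, true_p in props.items():
            assert abs(result.proportions.iloc[0][t] - true_p) < 0.05

    def test_recovery_error_shrinks_with_depth(self, three_type_setup):
        """Median recovery error decreases from depth 1e4 to 1e6."""
        truth, norm = three_type_setup
        vec = [0.6, 0.3, 0.1]
        errors = {}
        for depth in (10_000, 1_000_000):
            errs = []
            for seed in range(8):
                bulk = dbk.simulate_bulk(truth, vec, depth=depth, seed=100 + seed)
                res = deconvolve(bulk, norm, norm.obs["true_type"])
                est = res.proportions.iloc[0][list(truth.type_names)].to_numpy()
                errs.append(np.abs(est - np.array(vec)).max())
            errors[depth] = np.median(errs)
        assert errors[1_000_000] <= errors[10_000]

    def test_shared_markers_removed(self):
        """A gene passing the marker thresholds in two types is dropped.

        One-vs-rest dilutes the fold change of a gene shared by 2 of 3
        equal-size types to at most ln 2, so the threshold here is 0.5 to
        let the sharing itself (not the effect size) decide.
        """
        rng = np.random.default_rng(7)
        X = rng.poisson(0.2, size=(60, 30)).astype(float)
        X[:40, 0] = 5.0   # shared between A and B
        X[:20, 1] = 5.0   # unique to A
        X[20:40, 2] = 5.0  # unique to B
        X[40:, 3] = 5.0   # unique to C
        adata = make_adata(X)
        labels = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        from dbk.stats import select_deconvolution_markers

        markers = select_deconvolution_markers(
            adata, pd.Series(labels, index=adata.obs_names),
            marker_logfc=0.5, marker_min_pct=0.5,
        )
        all_markers = [g for gs in markers.values() for g in gs]
        assert "g0" not in all_markers
        assert "g1" in markers.get("A", [])

    def test_simplex_constraint(self, three_type_setup):
        truth, norm = three_type_setup
        bulk = dbk.simulate_bulk(truth, [0.5, 0.25, 0.25], depth=200_000, seed=45)
        result = deconvolve(bulk, norm, norm.obs["true_type"])
        p = result.proportions.to_numpy()
        assert (p >= -1e-12).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
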
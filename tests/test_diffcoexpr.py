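"""Differential co-expression: correlations, permutation null,
nine-class taxonomy, quadrants and rewired-pair extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netpert.diffcoexpr import (
    RewiredPairSet,
    add_quadrants,
    classify_pairs,
    classify_states,
    condition_correlations,
    empirical_null,
    empirical_pvalue,
    quadrant_of,
    sign_change_genes,
    significant_pairs,
)
from netpert.preprocess import ExpressionMatrix
from netpert.simulate import SimConfig, generate_expression


def expr_from(x_normal, x_tumor, genes=None):
    g = genes or [f"g{i}" for i in range(x_normal.shape[0])]
    cols_n = [f"n{j}" for j in range(x_normal.shape[1])]
    cols_t = [f"t{j}" for j in range(x_tumor.shape[1])]
    values = pd.DataFrame(
        np.hstack([x_normal, x_tumor]), index=g, columns=cols_n + cols_t
    )
    design = pd.Series(["normal"] * len(cols_n) + ["tumor"] * len(cols_t),
                       index=values.columns)
    return ExpressionMatrix(values, design, unit="log2")


@pytest.fixture(scope="module")
def null_expr():
    rng = np.random.default_rng(8)
    return expr_from(rng.standard_normal((30, 20)), rng.standard_normal((30, 40)))


class TestConditionCorrelations:
    def test_self_pair_has_zero_dz(self, null_expr):
        rec = condition_correlations(null_expr, pairs=[("g0", "g0")])
        assert rec.iloc[0]["r_normal"] == pytest.approx(1.0)
        assert rec.iloc[0]["r_tumor"] == pytest.approx(1.0)
        assert rec.iloc[0]["dz"] == pytest.approx(0.0)

    def test_all_pairs_count(self, null_expr):
        rec = condition_correlations(null_expr, pairs="all")
        g = len(null_expr.genes)
        assert len(rec) == g * (g - 1) // 2

    def test_planted_pair_estimates_within_sampling_bounds(self):
        """Sample correlations of a planted bivariate-normal pair land
        within Fisher-z sampling error of the targets."""
        rng = np.random.default_rng(21)

        def bivariate(rho, n):
            z = rng.standard_normal((2, n))
            return np.vstack([z[0], rho * z[0] + np.sqrt(1 - rho**2) * z[1]])

        xn = np.vstack([bivariate(-0.4, 56), rng.standard_normal((2, 56))])
        xt = np.vstack([bivariate(0.99, 500), rng.standard_normal((2, 500))])
        rec = condition_correlations(expr_from(xn, xt), pairs=[("g0", "g1")])
        assert rec.iloc[0]["r_normal"] == pytest.approx(-0.4, abs=0.15)
        assert rec.iloc[0]["r_tumor"] == pytest.approx(0.99, abs=0.01)

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(9)
        xn = rng.standard_normal((5, 10))
        xt = rng.standard_normal((5, 10))
        xn[2] = 3.0  # constant in normal condition
        with pytest.warns(UserWarning, match="constant"):
            rec = condition_correlations(expr_from(xn, xt), pairs="all")
        genes = set(rec["gene1"]) | set(rec["gene2"])
        assert "g2" not in genes
        assert len(rec) == 4 * 3 // 2

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="4 samples"):
            condition_correlations(
                expr_from(rng.standard_normal((4, 3)), rng.standard_normal((4, 10)))
            )


class TestEmpiricalNull:
    def test_pool_size(self, null_expr):
        rec = condition_correlations(null_expr, pairs="all")
        null = empirical_null(null_expr, rec, n_perm=3, seed=0)
        assert null.size == len(rec) * 3

    def test_seed_reproducible(self, null_expr):
        rec = condition_correlations(null_expr, pairs="all")
        a = empirical_null(null_expr, rec, n_perm=2, seed=5)
        b = empirical_null(null_expr, rec, n_perm=2, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_zero_permutations_rejected(self, null_expr):
        rec = condition_correlations(null_expr, pairs="all")
        with pytest.raises(ValueError, match="asymptotic"):
            empirical_null(null_expr, rec, n_perm=0)

    def test_null_data_observed_matches_pool(self, null_expr):
        """Without condition effects the observed dz distribution is
        indistinguishable from the permutation pool."""
        rec = condition_correlations(null_expr, pairs="all")
        null = empirical_null(null_expr, rec, n_perm=5, seed=1)
        ks = sps.ks_2samp(rec["dz"].to_numpy(), null)
        assert ks.pvalue > 0.01


class TestEmpiricalPvalue:
    def test_zero_dz_gives_one(self):
        null = np.array([0.5, -1.0, 2.0])
        p, flag = empirical_pvalue(0.0, null)
        assert p[0] == pytest.approx(1.0)
        assert not flag[0]

    def test_floor_falls_back_to_asymptotic(self):
        null = np.linspace(-1, 1, 999)
        p, flag = empirical_pvalue(25.0, null)
        assert flag[0]
        assert p[0] == pytest.approx(2 * sps.norm.sf(25.0))
        assert p[0] < 1 / 1000

    def test_uniform_under_null(self):
        rng = np.random.default_rng(2)
        null = rng.standard_normal(20000)
        obs = rng.standard_normal(2000)
        p, _ = empirical_pvalue(obs, null)
        assert p.mean() == pytest.approx(0.5, abs=0.02)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.array([]))


class TestClassification:
    def test_table_style_sign_flip(self):
        # strong negative-to-positive flip: ('-','+') and quadrant II
        assert classify_states(-0.388, 0.003) == "-"
        assert classify_states(0.992, 1e-300) == "+"
        assert quadrant_of(-0.388, 0.992) == "II"

    def test_nonsignificant_both(self):
        assert classify_states(0.3, 0.4) == "0"

    def test_grid_hits_all_nine_labels(self):
        states = {"+": (0.8, 0.001), "0": (0.1, 0.5), "-": (-0.8, 0.001)}
        rows = []
        for sn, (rn, pn) in states.items():
            for st_, (rt, pt) in states.items():
                rows.append((rn, pn, rt, pt, f"{sn}/{st_}"))
        df = pd.DataFrame(
            rows, columns=["r_normal", "p_normal", "r_tumor", "p_tumor", "expect"]
        )
        assert list(classify_pairs(df)) == list(df["expect"])

    @pytest.mark.parametrize(
        "rn,rt,expect",
        [(-0.388, 0.992, "II"), (0.5, -0.5, "IV"), (0.5, 0.5, "I"),
         (-0.5, -0.5, "III"), (0.0, 0.5, "axis")],
    )
    def test_quadrants(self, rn, rt, expect):
        assert quadrant_of(rn, rt) == expect

    def test_class9_quadrant_consistency_and_swap(self):
        """('-','+') implies quadrant II; swapping conditions transposes
        the label and maps II to IV."""
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "r_normal": rng.uniform(-1, 1, 200),
                "p_normal": rng.uniform(0, 1, 200),
                "r_tumor": rng.uniform(-1, 1, 200),
                "p_tumor": rng.uniform(0, 1, 200),
            }
        )
        cls = classify_pairs(df)
        quad = add_quadrants(df)
        for c, q in zip(cls, quad):
            if c == "-/+":
                assert q == "II"
            if c == "+/-":
                assert q == "IV"
        swapped = df.rename(
            columns={"r_normal": "r_tumor", "r_tumor": "r_normal",
                     "p_normal": "p_tumor", "p_tumor": "p_normal"}
        )
        cls_s = classify_pairs(swapped)
        quad_s = add_quadrants(swapped)
        assert all(a == b[::-1] for a, b in zip(cls_s, cls))
        trans = {"II": "IV", "IV": "II", "I": "I", "III": "III", "axis": "axis"}
        assert all(qs == trans[q] for qs, q in zip(quad_s, quad))


class TestSignificantPairs:
    def base_records(self):
        return pd.DataFrame(
            {
                "gene1": ["a", "a", "b"],
                "gene2": ["b", "c", "c"],
                "r_normal": [-0.5, 0.5, 0.2],
                "p_normal": [0.01, 0.01, 0.4],
                "r_tumor": [0.9, -0.9, 0.3],
                "p_tumor": [1e-10, 1e-10, 0.3],
                "dz": [-10.0, 11.0, -0.4],
                "p_diff_asymptotic": [1e-23, 1e-28, 0.7],
                "p_diff_empirical": [1e-23, 1e-28, 0.7],
            }
        )

    def test_threshold_above_all_keeps_everything(self):
        ps = significant_pairs(self.base_records(), threshold=1.1)
        assert len(ps.records) == 3
        assert ps.unique_genes == ["a", "b", "c"]

    def test_threshold_zero_empties(self):
        assert len(significant_pairs(self.base_records(), threshold=0.0).records) == 0

    def test_quadrant_counts(self):
        ps = significant_pairs(self.base_records(), threshold=1e-20)
        assert ps.quadrant_counts["II"] == 1
        assert ps.quadrant_counts["IV"] == 1
        assert len(ps.records) == 2

    def test_planted_rewired_recovery(self):
        """20 sign-flip pairs (r -0.5 -> +0.9, n 60/500) among ~1000
        null pairs: all recovered at the 1e-20 asymptotic threshold with
        at most one false positive."""
        cfg = SimConfig(
            n_genes=66, n_normal=60, n_tumor=500, n_deg_up=0, n_deg_down=0,
            rewired_blocks=[(20, -0.5, 0.9)], coexpr_modules=[], seed=31,
        )
        _, norm, truth = generate_expression(cfg)
        logged = ExpressionMatrix(np.log2(norm.values + 1), norm.design, "log2")
        rec = condition_correlations(logged, pairs="all")
        ps = significant_pairs(rec, threshold=1e-20, use="asymptotic")
        planted = {tuple(sorted(p[:2])) for p in truth.rewired_pairs}
        found = {tuple(sorted(t)) for t in zip(ps.records.gene1, ps.records.gene2)}
        assert planted <= found
        assert len(found - planted) <= 1


class TestSignChangeGenes:
    def test_single_quadrant_ii_record(self):
        rec = pd.DataFrame(
            {"gene1": ["A"], "gene2": ["B"], "r_normal": [-0.5], "r_tumor": [0.9],
             "quadrant": ["II"]}
        )
        assert sign_change_genes(RewiredPairSet(rec)) == {"A", "B"}

    def test_quadrant_i_only_is_empty(self):
        rec = pd.DataFrame(
            {"gene1": ["A"], "gene2": ["B"], "r_normal": [0.5], "r_tumor": [0.9],
             "quadrant": ["I"]}
        )
        assert sign_change_genes(RewiredPairSet(rec)) == set()

    def test_shared_genes_counted_once(self):
        rec = pd.DataFrame(
            {
                "gene1": ["A", "A"],
                "gene2": ["B", "C"],
                "r_normal": [-0.5, -0.6],
                "r_tumor": [0.9, 0.8],
                "quadrant": ["II", "II"],
            }
        )
        genes = sign_change_genes(RewiredPairSet(rec))
        assert genes == {"A", "B", "C"}
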
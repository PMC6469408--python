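"""ΔCq arithmetic, ANOVA, Scheffé post-hoc, FDR and letter displays."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hmscreen.expression import (
    anova_per_gene,
    bh_fdr,
    compute_delta_cq,
    letter_display,
    primer_efficiency,
    scheffe_pairwise,
    summarize_counts,
    two_way_anova,
)


def _cq_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "sample_class", "replicate", "reference_gene", "cq_reference", "cq_target"]
    )


class TestDeltaCq:
    def test_identity_and_direct_arithmetic(self):
        df = _cq_frame(
            [
                ("g", "a", "r1", "RpL32", 20.0, 20.0),
                ("g", "a", "r2", "RpL32", 20.0, 31.14),
            ]
        )
        out = compute_delta_cq(df)
        assert out["delta_cq"].tolist() == pytest.approx([0.0, -11.14])

    def test_antisymmetry_under_swap(self):
        df = _cq_frame([("g", "a", "r1", "RpL32", 18.3, 24.9)])
        swapped = df.rename(columns={"cq_reference": "cq_target", "cq_target": "cq_reference"})
        d1 = compute_delta_cq(df)["delta_cq"].iloc[0]
        d2 = compute_delta_cq(swapped)["delta_cq"].iloc[0]
        assert d1 == pytest.approx(-d2)

    def test_non_finite_rows_rejected_and_counted(self):
        df = _cq_frame(
            [("g", "a", "r1", "RpL32", 20.0, 25.0), ("g", "a", "r2", "RpL32", np.nan, 25.0)]
        )
        out = compute_delta_cq(df)
        assert len(out) == 1
        assert out.attrs["n_rejected"] == 1


class TestPrimerEfficiency:
    def test_perfect_doubling(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        slope = -1 / np.log10(2)  # one cycle per doubling
        _, eff = primer_efficiency(x, 20 + slope * x)
        assert eff == pytest.approx(1.0, abs=1e-9)

    def test_slope_minus_3_6(self):
        x = np.array([0.0, -1.0, -2.0])
        _, eff = primer_efficiency(x, 20 - 3.6 * x)
        assert eff == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            primer_efficiency([0.0, -1.0], [20, 23])
        with pytest.raises(ValueError):
            primer_efficiency([0.0, 0.0, 0.0], [20, 21, 22])
        with pytest.raises(ValueError):
            primer_efficiency([0.0, -1.0, -2.0], [20.0, 20.0, 20.0])


def _two_way_frame(effects, n_rep=4, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for gene, ref, mean in effects:
        for r in range(n_rep):
            rows.append(
                {
                    "gene": gene,
                    "sample_class": "mrt",
                    "replicate": f"r{r}",
                    "reference_gene": ref,
                    "delta_cq": mean + rng.normal(0, sd),
                }
            )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_null_data_gives_zero_f(self):
        df = _two_way_frame(
            [(g, r, 1.5) for g in "ab" for r in ("RpL32", "RpS18")]
        )
        for res in two_way_anova(df):
            assert res.f_statistic == 0.0
            assert res.p_value == 1.0

    def test_matches_sum_of_squares_oracle(self):
        # balanced 3 genes x 2 references x 4 replicates with noise
        effects = [
            (g, r, dg + dr)
            for (g, dg), (r, dr) in itertools.product(
                [("g1", 0.0), ("g2", 1.0), ("g3", -2.0)], [("RpL32", 0.0), ("RpS18", 0.7)]
            )
        ]
        df = _two_way_frame(effects, sd=0.4, seed=42)
        results = {r.effect: r for r in two_way_anova(df)}

        # independent partition of sums of squares for the balanced design
        y = df["delta_cq"].to_numpy()
        grand = y.mean()
        a_lab = df["gene"].to_numpy()
        b_lab = df["reference_gene"].to_numpy()
        ssa = sum(
            (df[a_lab == a].shape[0]) * (y[a_lab == a].mean() - grand) ** 2
            for a in np.unique(a_lab)
        )
        ssb = sum(
            (df[b_lab == b].shape[0]) * (y[b_lab == b].mean() - grand) ** 2
            for b in np.unique(b_lab)
        )
        ss_cells = sum(
            ((a_lab == a) & (b_lab == b)).sum()
            * (y[(a_lab == a) & (b_lab == b)].mean() - grand) ** 2
            for a in np.unique(a_lab)
            for b in np.unique(b_lab)
        )
        ssab = ss_cells - ssa - ssb
        sse = ((y - grand) ** 2).sum() - ss_cells
        df_a, df_b = 2, 1
        df_ab, df_e = 2, len(y) - 6
        for effect, ss, d in [("gene", ssa, df_a), ("reference_gene", ssb, df_b), ("gene:reference_gene", ssab, df_ab)]:
            f_oracle = (ss / d) / (sse / df_e)
            assert results[effect].f_statistic == pytest.approx(f_oracle, rel=1e-10)
            assert results[effect].df_num == d
            assert results[effect].df_den == df_e

    def test_additive_reference_offset_rarely_fakes_interaction(self):
        """With a purely additive reference shift the interaction F should sit
        below its 95% critical value in the vast majority of datasets."""
        crit = stats.f.ppf(0.95, 2, 18)
        below = 0
        n_seeds = 200
        effects = [
            (g, r, dg + dr)
            for (g, dg), (r, dr) in itertools.product(
                [("g1", 0.0), ("g2", 1.0), ("g3", -2.0)], [("RpL32", 0.0), ("RpS18", 0.7)]
            )
        ]
        for seed in range(n_seeds):
            df = _two_way_frame(effects, sd=0.3, seed=seed)
            inter = [r for r in two_way_anova(df) if r.effect == "gene:reference_gene"][0]
            below += inter.f_statistic < crit
        assert below / n_seeds >= 0.9

    def test_empty_cell_named_in_error(self):
        df = _two_way_frame(
            [("g1", "RpL32", 0.0), ("g1", "RpS18", 0.0), ("g2", "RpL32", 0.0)]
        )
        with pytest.raises(ValueError, match="g2"):
            two_way_anova(df)


def _oneway_frame(groups, reference="RpL32"):
    rows = []
    for cls, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "gene": "g",
                    "sample_class": cls,
                    "replicate": f"r{i}",
                    "reference_gene": reference,
                    "delta_cq": float(v),
                }
            )
    return pd.DataFrame(rows)


class TestAnovaPerGene:
    def test_identical_classes_give_zero_f(self):
        df = _oneway_frame({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        res = anova_per_gene(df, "g")
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_textbook_oracle(self):
        # hand-computed: groups (1,2,3), (2,3,4), (6,7,8)
        # grand mean 4; SSB = 3*(2-4)^2 + 3*(3-4)^2 + 3*(7-4)^2 = 42
        # SSE = 2 + 2 + 2 = 6; F = (42/2)/(6/6) = 21
        df = _oneway_frame({"a": [1, 2, 3], "b": [2, 3, 4], "c": [6, 7, 8]})
        res = anova_per_gene(df, "g")
        assert res.f_statistic == pytest.approx(21.0, rel=1e-12)
        assert res.df_num == 2 and res.df_den == 6
        assert res.p_value == pytest.approx(stats.f.sf(21.0, 2, 6), rel=1e-12)

    def test_pooled_references_match_oracle_under_balance(self):
        """Centering within reference + df correction equals the additive
        class + reference two-way fit (statsmodels as the oracle)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        rows = []
        for ref, off in [("RpL32", 0.0), ("RpS18", 0.9)]:
            for cls, m in [("a", 0.0), ("b", 0.5), ("c", -0.3)]:
                for i in range(4):
                    rows.append(
                        {
                            "gene": "g",
                            "sample_class": cls,
                            "replicate": f"r{i}",
                            "reference_gene": ref,
                            "delta_cq": m + off + rng.normal(0, 0.4),
                        }
                    )
        df = pd.DataFrame(rows)
        res = anova_per_gene(df, "g", pool_references=True)
        fit = smf.ols("delta_cq ~ C(sample_class) + C(reference_gene)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res.f_statistic == pytest.approx(table.loc["C(sample_class)", "F"], rel=1e-10)
        assert res.df_den == int(table.loc["Residual", "df"])

    def test_single_replicate_class_named(self):
        df = _oneway_frame({"a": [1, 2, 3], "b": [2.0]})
        with pytest.raises(ValueError, match="b"):
            anova_per_gene(df, "g")


class TestScheffe:
    def test_equal_group_means_give_unit_p(self):
        df = _oneway_frame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [0.0, 1.0, 2.0]})
        mat, _ = scheffe_pairwise(df, "g")
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_two_groups_reduce_to_pooled_f_test(self):
        df = _oneway_frame({"a": [1.0, 2.0, 3.5], "b": [4.0, 5.5, 6.0]})
        mat, _ = scheffe_pairwise(df, "g")
        a, b = [1.0, 2.0, 3.5], [4.0, 5.5, 6.0]
        t, p = stats.ttest_ind(a, b)  # pooled-variance two-sample test
        assert mat.loc["a", "b"] == pytest.approx(p, rel=1e-10)

    def test_matches_hand_worked_example(self):
        # three groups of four with unit within-group spread:
        # means 10, 12, 15; per-group SS = 5 -> MSE = 15/9
        groups = {
            "a": [8.5, 9.5, 10.5, 11.5],
            "b": [10.5, 11.5, 12.5, 13.5],
            "c": [13.5, 14.5, 15.5, 16.5],
        }
        df = _oneway_frame(groups)
        mat, _ = scheffe_pairwise(df, "g")
        mse = 15 / 9
        for gi, gj in [("a", "b"), ("a", "c"), ("b", "c")]:
            diff = np.mean(groups[gi]) - np.mean(groups[gj])
            s = diff**2 / (mse * (1 / 4 + 1 / 4) * 2)
            assert mat.loc[gi, gj] == pytest.approx(stats.f.sf(s, 2, 9), rel=1e-12)

    def test_conservative_relative_to_unadjusted_pairwise_f(self, rng):
        """Scheffé protects all contrasts simultaneously, so its p can never
        undercut the unadjusted pairwise F test on the same pooled error."""
        for _ in range(20):
            k = int(rng.integers(3, 6))
            groups = {
                f"c{i}": rng.normal(rng.normal(0, 1), 0.5, 5).tolist() for i in range(k)
            }
            df = _oneway_frame(groups)
            mat, _ = scheffe_pairwise(df, "g")
            y = df["delta_cq"].to_numpy()
            cls = df["sample_class"].to_numpy()
            mse = np.mean(
                [np.var(y[cls == c], ddof=1) for c in groups]
            )  # balanced pooled MSE
            df_den = y.size - k
            names = list(groups)
            for i, j in itertools.combinations(names, 2):
                diff = np.mean(groups[i]) - np.mean(groups[j])
                f_unadj = diff**2 / (mse * (2 / 5))
                p_unadj = stats.f.sf(f_unadj, 1, df_den)
                assert mat.loc[i, j] >= p_unadj - 1e-12

    def test_zero_mse_definition(self):
        df = _oneway_frame({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [1.0, 1.0]})
        mat, _ = scheffe_pairwise(df, "g")
        assert mat.loc["a", "b"] == 0.0
        assert mat.loc["a", "c"] == 1.0


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_q_dominates_p_and_monotone(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestLetterDisplay:
    @staticmethod
    def _matrix(classes, nonsig_pairs):
        k = len(classes)
        m = np.eye(k, dtype=bool)
        for i, j in nonsig_pairs:
            m[i, j] = m[j, i] = True
        return pd.DataFrame(m, index=classes, columns=classes)

    def test_all_nonsignificant_single_letter(self):
        mat = self._matrix(list("ABC"), [(0, 1), (0, 2), (1, 2)])
        assert letter_display(mat) == {"A": "a", "B": "a", "C": "a"}

    def test_all_significant_distinct_letters(self):
        mat = self._matrix(list("ABC"), [])
        letters = letter_display(mat)
        assert len({letters[c] for c in "ABC"}) == 3
        assert all(len(v) == 1 for v in letters.values())

    def test_bridge_class_shares_both_letters(self):
        # A vs B significant; C not different from either
        mat = self._matrix(list("ABC"), [(0, 2), (1, 2)])
        assert letter_display(mat) == {"A": "a", "B": "b", "C": "ab"}

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_share_letter_iff_nonsignificant_exhaustive(self, k):
        classes = [f"c{i}" for i in range(k)]
        pairs = list(itertools.combinations(range(k), 2))
        for mask in range(2 ** len(pairs)):
            nonsig = [p for b, p in enumerate(pairs) if mask >> b & 1]
            mat = self._matrix(classes, nonsig)
            letters = letter_display(mat)
            for i, j in pairs:
                share = bool(set(letters[classes[i]]) & set(letters[classes[j]]))
                assert share == bool(mat.iloc[i, j]), (nonsig, letters)

    def test_asymmetric_rejected(self):
        mat = pd.DataFrame(
            [[True, True], [False, True]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError):
            letter_display(mat)


class TestSummarizeCounts:
    def test_sterile_class_all_zero(self):
        df = pd.DataFrame({"sample_class": ["x"] * 6, "count": [0] * 6})
        out = summarize_counts(df)
        assert out.loc[0, "mean"] == 0.0 and out.loc[0, "se"] == 0.0

    def test_hand_computed(self):
        df = pd.DataFrame({"sample_class": ["x"] * 3, "count": [1, 2, 3]})
        out = summarize_counts(df)
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "se"] == pytest.approx(1 / np.sqrt(3), abs=1e-9)

    def test_single_count(self):
        df = pd.DataFrame({"sample_class": ["x"], "count": [7]})
        out = summarize_counts(df)
        assert out.loc[0, "mean"] == 7.0 and out.loc[0, "se"] == 0.0
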
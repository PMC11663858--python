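import numpy as np
import pandas as pd
import pytest

import adipoquant as aq


def tidy(groups):
    return pd.DataFrame([{"value": v, "group": g}
                         for g, vals in groups.items() for v in vals])


class TestKruskalWallis:
    def test_identical_values_no_effect(self):
        res = aq.kruskal_wallis_multi(tidy({"a": [5, 5, 5], "b": [5, 5, 5]}))
        assert res.h == 0.0 and res.p_value == 1.0
        assert (res.pairwise.p_adj == 1.0).all()

    def test_hand_computed_h(self):
        # ranks 1..9 split into consecutive triples:
        # H = 12/(9*10) * (36/3 + 225/3 + 576/3) - 3*10 = 7.2
        res = aq.kruskal_wallis_multi(tidy({
            "a": [1, 2, 3], "b": [101, 102, 103], "c": [201, 202, 203]}))
        assert res.h == pytest.approx(7.2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        table = tidy({"a": rng.normal(size=8), "b": rng.normal(size=8),
                      "c": rng.normal(1, 1, size=8)})
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert aq.kruskal_wallis_multi(table).h == \
            pytest.approx(aq.kruskal_wallis_multi(shuffled).h)

    def test_small_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="tiny"):
            aq.kruskal_wallis_multi(tidy({"a": [1, 2, 3], "tiny": [4]}))

    def test_pairwise_structure_and_holm(self):
        rng = np.random.default_rng(1)
        res = aq.kruskal_wallis_multi(tidy({
            "a": rng.normal(size=10), "b": rng.normal(size=10),
            "c": rng.normal(3, 1, size=10)}))
        assert len(res.pairwise) == 3  # all unordered pairs
        assert (res.pairwise.p_adj >= res.pairwise.p_raw - 1e-12).all()
        assert (res.pairwise.p_adj <= 1.0).all()


class TestTwoWayAnova:
    @staticmethod
    def table(values):
        rows = []
        for (a, b), obs in values.items():
            rows += [{"value": v, "factor_a": a, "factor_b": b} for v in obs]
        return pd.DataFrame(rows)

    def test_zero_variance_gives_zero_f(self):
        res = aq.two_way_anova(self.table({
            ("wt", "std"): [3, 3], ("wt", "adipo"): [3, 3],
            ("ko", "std"): [3, 3], ("ko", "adipo"): [3, 3]}))
        effects = res.table.drop(index="Residual")
        assert (effects["F"] == 0).all() and (effects["p"] == 1).all()

    def test_balanced_2x2_matches_closed_form(self):
        # cell means: wt/std 10, wt/adipo 14, ko/std 12, ko/adipo 20; 2 reps, +-1
        data = {("wt", "std"): [9, 11], ("wt", "adipo"): [13, 15],
                ("ko", "std"): [11, 13], ("ko", "adipo"): [19, 21]}
        res = aq.two_way_anova(self.table(data))
        # closed-form balanced ANOVA from cell means
        means = {k: np.mean(v) for k, v in data.items()}
        grand = np.mean(list(means.values()))
        r = 2  # replicates per cell
        a_means = {a: np.mean([means[(a, b)] for b in ("std", "adipo")]) for a in ("wt", "ko")}
        b_means = {b: np.mean([means[(a, b)] for a in ("wt", "ko")]) for b in ("std", "adipo")}
        ss_a = 2 * r * sum((m - grand) ** 2 for m in a_means.values())
        ss_b = 2 * r * sum((m - grand) ** 2 for m in b_means.values())
        ss_ab = r * sum((means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
                        for a in ("wt", "ko") for b in ("std", "adipo"))
        ss_err = sum((v - means[k]) ** 2 for k, vals in data.items() for v in vals)
        ms_err = ss_err / 4  # df = 8 - 4
        assert res.table.loc["factor_a", "F"] == pytest.approx(ss_a / ms_err)
        assert res.table.loc["factor_b", "F"] == pytest.approx(ss_b / ms_err)
        assert res.table.loc["factor_a:factor_b", "F"] == pytest.approx(ss_ab / ms_err)

    def test_f_scale_invariance(self):
        rng = np.random.default_rng(2)
        data = {(a, b): rng.normal(size=3).tolist()
                for a in ("wt", "ko") for b in ("std", "adipo")}
        base = aq.two_way_anova(self.table(data))
        doubled = aq.two_way_anova(self.table(
            {k: [2 * v for v in vals] for k, vals in data.items()}))
        for eff in ("factor_a", "factor_b", "factor_a:factor_b"):
            assert doubled.table.loc[eff, "F"] == pytest.approx(base.table.loc[eff, "F"])

    def test_empty_cell_rejected(self):
        bad = self.table({("wt", "std"): [1, 2], ("wt", "adipo"): [3, 4],
                          ("ko", "std"): [5, 6]})
        with pytest.raises(ValueError):
            aq.two_way_anova(bad)

    def test_posthoc_tables_present(self):
        rng = np.random.default_rng(3)
        data = {(a, b): rng.normal(size=3).tolist()
                for a in ("wt", "ko") for b in ("std", "adipo")}
        res = aq.two_way_anova(self.table(data))
        assert set(res.posthoc) == {"factor_a", "factor_b", "cells"}


class TestDdct:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "ct"])

    def test_single_delta_example(self):
        t = self.table([("treated", "tcad", 25), ("treated", "ref", 20),
                        ("control", "tcad", 24), ("control", "ref", 20)])
        res = aq.ddct(t, reference_gene="ref", control_samples=["control"])
        treated = res[res["sample"] == "treated"].rel_expression.iloc[0]
        assert treated == pytest.approx(0.5)

    def test_ddct_minus_two_gives_four(self):
        t = self.table([("treated", "g", 22), ("treated", "ref", 20),
                        ("control", "g", 24), ("control", "ref", 20)])
        res = aq.ddct(t, reference_gene="ref", control_samples=["control"])
        assert res[res["sample"] == "treated"].rel_expression.iloc[0] == pytest.approx(4.0)

    def test_control_mean_is_exactly_one(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(3):
            rows += [(f"c{i}", "g", 20 + rng.uniform(-1, 1)), (f"c{i}", "ref", 18)]
        for i in range(3):
            rows += [(f"t{i}", "g", 19 + rng.uniform(-1, 1)), (f"t{i}", "ref", 18)]
        res = aq.ddct(self.table(rows), reference_gene="ref",
                      control_samples=["c0", "c1", "c2"])
        ctrl_mean = res[res.is_control].rel_expression.mean()
        assert abs(ctrl_mean - 1.0) < 1e-12

    def test_invariant_to_joint_ct_shift(self):
        rows = [("c", "g", 24.0), ("c", "ref", 20.0),
                ("t", "g", 22.5), ("t", "ref", 19.0)]
        base = aq.ddct(self.table(rows), "ref", ["c"])
        shifted = aq.ddct(self.table([(s, g, ct + 3.0) for s, g, ct in rows]),
                          "ref", ["c"])
        pd.testing.assert_series_equal(base.rel_expression, shifted.rel_expression)

    def test_missing_reference_rejected(self):
        t = self.table([("c", "g", 24), ("c", "ref", 20), ("t", "g", 22)])
        with pytest.raises(ValueError, match="reference"):
            aq.ddct(t, reference_gene="ref", control_samples=["c"])

    def test_nonpositive_ct_rejected(self):
        t = self.table([("c", "g", 0.0), ("c", "ref", 20)])
        with pytest.raises(ValueError):
            aq.ddct(t, reference_gene="ref", control_samples=["c"])


class TestEluateAndStandardCurve:
    def test_normalized_eluate(self):
        assert aq.normalize_eluate(0.5, 2.0) == pytest.approx(0.25)

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            aq.normalize_eluate(0.5, 0.0)

    def test_exact_linear_inversion(self):
        curve = aq.fit_standard_curve([(c, 0.1 * c) for c in (1, 2, 4, 8)])
        assert curve.predict_conc(0.35) == pytest.approx(3.5)

    def test_duplicates_averaged(self):
        # duplicate pairs average onto the same exact line
        curve = aq.fit_standard_curve([(1, 0.09), (1, 0.11), (2, 0.19), (2, 0.21)])
        assert curve.slope == pytest.approx(0.1)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            aq.fit_standard_curve([(1, 0.5), (2, 0.5), (3, 0.5)])
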
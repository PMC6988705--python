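import numpy as np
import pandas as pd
import pytest
from scipy import stats

from craniomirror.simulate import LarvaSpec, generate_larvae
from craniomirror.zebrafish import (anova_tukey, group_compare,
                                    majority_direction_test,
                                    normalize_to_controls, summarize_conditions,
                                    synergy_test)

from oracles import binom_tail_exact, pooled_t_pvalue


def _batch(conditions, n=30, sd=6.0, control_mean=80.0, seed=0):
    spec = LarvaSpec(conditions=conditions, n_per_condition=n, sd_deg=sd,
                     control_mean_deg=control_mean, seed=seed)
    batch, _ = generate_larvae(spec)
    return batch


class TestNormalization:
    def test_worked_example(self):
        batch = pd.DataFrame({
            "condition": ["uninjected"] * 2 + ["G"],
            "cha_deg": [78.0, 82.0, 84.0],  # control mean 80
        })
        out = normalize_to_controls(batch)
        assert out["cha_norm"].iloc[2] == pytest.approx(105.0)

    def test_control_mean_exactly_100(self):
        batch = _batch({"A": -3.0, "B": 2.0}, seed=1)
        out = normalize_to_controls(batch)
        ctrl = out.loc[out["condition"] == "uninjected", "cha_norm"]
        assert ctrl.mean() == pytest.approx(100.0, abs=1e-12)

    def test_scale_equivariance(self):
        batch = _batch({"A": -3.0}, seed=2)
        out1 = normalize_to_controls(batch)
        scaled = batch.assign(cha_deg=batch["cha_deg"] * 1.7)
        out2 = normalize_to_controls(scaled)
        assert np.allclose(out1["cha_norm"], out2["cha_norm"], atol=1e-12)

    def test_idempotent_on_normalized_column(self):
        batch = _batch({"A": -3.0}, seed=3)
        once = normalize_to_controls(batch)
        twice = normalize_to_controls(once, response="cha_norm", out="cha_norm2")
        assert np.allclose(once["cha_norm"], twice["cha_norm2"], atol=1e-12)

    def test_no_controls_raises(self):
        with pytest.raises(ValueError, match="control"):
            normalize_to_controls(pd.DataFrame({"condition": ["A"],
                                                "cha_deg": [90.0]}))


class TestAnovaTukey:
    def test_two_groups_tukey_equals_pooled_t(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(100, 6, int(rng.integers(5, 40)))
            b = rng.normal(97, 6, int(rng.integers(5, 40)))
            res = anova_tukey({"uninjected": a, "G": b})
            assert res.pairwise["p_adj"].iloc[0] == pytest.approx(
                pooled_t_pvalue(a, b), abs=1e-6)

    def test_tukey_at_least_unadjusted_pairwise_t(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            groups = {f"g{i}": rng.normal(100, 6, 20) for i in range(4)}
            res = anova_tukey(groups)
            for _, row in res.pairwise.iterrows():
                p_t = pooled_t_pvalue(groups[row["group1"]], groups[row["group2"]])
                assert row["p_adj"] >= p_t - 1e-9

    @staticmethod
    def _q_stats(arrays):
        """Pairwise studentized-range statistics (the quantity Tukey's
        adjusted p is a tail probability of)."""
        k = len(arrays)
        ns = np.array([len(a) for a in arrays])
        means = np.array([a.mean() for a in arrays])
        df = int(ns.sum() - k)
        s2 = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
        qs = {}
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(s2 / 2 * (1 / ns[i] + 1 / ns[j]))
                qs[(i, j)] = abs(means[i] - means[j]) / se
        return qs, df

    def test_tukey_rejection_equals_critical_value_rule(self):
        # "adjusted p < alpha" must coincide exactly with comparing the
        # pairwise studentized-range statistic to its alpha critical value
        rng = np.random.default_rng(6)
        for rep in range(15):
            arrays = [rng.normal(100, 6, 20) for _ in range(4)]
            res = anova_tukey({f"g{i}": a for i, a in enumerate(arrays)})
            qs, df = self._q_stats(arrays)
            crit = stats.studentized_range.ppf(0.95, 4, df)
            names = [f"g{i}" for i in range(4)]
            for _, row in res.pairwise.iterrows():
                i, j = names.index(row["group1"]), names.index(row["group2"])
                assert (row["p_adj"] < 0.05) == (qs[(i, j)] > crit)
            f_ref, p_ref = stats.f_oneway(*arrays)
            assert res.p_value == pytest.approx(p_ref)

    def test_null_anova_p_uniform_and_tukey_fwer_controlled(self):
        # 2000 null replicates; the Tukey rejection rule is applied in its
        # equivalent critical-value form (verified equivalent above)
        rng = np.random.default_rng(6)
        n_rep = 2000
        ps, any_rej = [], 0
        crit = stats.studentized_range.ppf(0.95, 4, 4 * 20 - 4)
        for _ in range(n_rep):
            arrays = [rng.normal(100, 6, 20) for _ in range(4)]
            ps.append(stats.f_oneway(*arrays)[1])
            qs, _ = self._q_stats(arrays)
            any_rej += max(qs.values()) > crit
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert any_rej / n_rep <= 0.06

    def test_power_for_planted_shift(self):
        # -4 degree shift at condition n=60 vs a large uninjected control
        # group (n=200), SD 6: Tukey-adjusted p < 0.01 nearly always
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            groups = {
                "uninjected": rng.normal(100, 6, 200),
                "HIT": rng.normal(96, 6, 60),
                "NULL": rng.normal(100, 6, 60),
            }
            vc = anova_tukey(groups).vs_control()
            hits += vc.loc[vc["condition"] == "HIT", "p_adj"].iloc[0] < 0.01
        assert hits >= int(0.90 * n_rep)

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestMajorityDirectionTest:
    def test_24_of_30_below_printed_bound(self):
        effects = {f"g{i}": -1.0 for i in range(24)} | {f"h{i}": 1.0 for i in range(6)}
        k, n, p = majority_direction_test(effects)
        assert (k, n) == (24, 30)
        assert p == pytest.approx(float(binom_tail_exact(24, 30)), abs=1e-12)
        assert p < 0.001

    def test_even_split(self):
        effects = {f"g{i}": (-1.0 if i < 15 else 1.0) for i in range(30)}
        _, _, p = majority_direction_test(effects)
        assert p == pytest.approx(float(binom_tail_exact(15, 30)), abs=1e-12)
        assert p == pytest.approx(0.572, abs=0.001)

    def test_unanimous(self):
        effects = {f"g{i}": -1.0 for i in range(30)}
        _, _, p = majority_direction_test(effects)
        assert p == pytest.approx(2.0 ** -30, rel=1e-9)

    def test_positive_direction_option(self):
        effects = {"a": 1.0, "b": 1.0, "c": -1.0}
        k, n, _ = majority_direction_test(effects, direction="positive")
        assert (k, n) == (2, 3)


class TestSynergy:
    @staticmethod
    def _synergy_batch(inter, n=50, seed=0, genes=("A", "B", "C")):
        conds = {}
        for r in range(1, len(genes) + 1):
            import itertools
            for combo in itertools.combinations(genes, r):
                conds["+".join(combo)] = 0.0
        spec = LarvaSpec(conditions=conds, n_per_condition=n, sd_deg=6.0,
                         interactions=inter, seed=seed)
        batch, _ = generate_larvae(spec)
        return normalize_to_controls(batch)

    def test_null_additive_p_uniform(self):
        ps = []
        for rep in range(300):
            batch = self._synergy_batch({}, n=20, seed=rep)
            ps.append(synergy_test(batch, ("A", "B", "C")).p_additive_vs_full)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_three_way_synergy_detected(self):
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            batch = self._synergy_batch({("A", "B", "C"): -5.0}, n=50, seed=rep)
            res = synergy_test(batch, ("A", "B", "C"))
            hits += res.p_additive_vs_full < 0.05
        assert hits >= int(0.80 * n_rep)

    def test_interaction_coefficient_recovered(self):
        batch = self._synergy_batch({("A", "B"): -8.0}, n=200, seed=1,
                                    genes=("A", "B"))
        res = synergy_test(batch, ("A", "B"))
        coef = res.interaction_coefs.set_index("term").loc["A:B", "coef"]
        # -8 degrees raw, expressed in control-anchored units (~x100/85)
        assert coef == pytest.approx(-8.0 * 100 / 85.0, abs=2.5)

    def test_single_gene_set_refused(self):
        batch = self._synergy_batch({}, n=10, genes=("A", "B"))
        with pytest.raises(ValueError, match="at least 2 genes"):
            synergy_test(batch, ("A",))

    def test_missing_cells_listed(self):
        batch = self._synergy_batch({}, n=10, genes=("A", "B"))
        batch = batch[batch["condition"] != "A+B"]
        with pytest.raises(ValueError, match="A\\+B"):
            synergy_test(batch, ("A", "B"))

    def test_zero_interactions_reproduce_additive_fit(self):
        batch = self._synergy_batch({}, n=30, seed=2, genes=("A", "B"))
        res = synergy_test(batch, ("A", "B"))
        # predictions of the full model with its interaction forced to zero
        # equal the additive fit applied to the same design
        add_params = np.asarray(res.additive_fit.params)
        full_params = np.asarray(res.full_fit.params).copy()
        full_params[-1] = 0.0
        # same main-effect design columns lead both models
        assert res.full_fit.model.exog.shape[1] == len(add_params) + 1


class TestGroupSummaries:
    def test_group_compare_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        diff, t, p = group_compare(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert (t, p) == pytest.approx((t_ref, p_ref))

    def test_summarize_conditions(self):
        batch = _batch({"A": -3.0}, n=10, seed=9)
        batch = normalize_to_controls(batch)
        summ = summarize_conditions(batch)
        assert set(summ["condition"]) == {"uninjected", "A"}
        assert (summ["n"] == 10).all()
        ctrl_mean = summ.loc[summ["condition"] == "uninjected", "mean"].iloc[0]
        assert ctrl_mean == pytest.approx(100.0, abs=1e-9)
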
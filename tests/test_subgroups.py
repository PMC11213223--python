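"""Down-sampling, Apriori mining (vs brute-force enumeration), Westfall-Young
permutation control and full-data subgroup metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cardioscreen import subgroups as sg
from cardioscreen.simulate import ConfigError


def brute_force_rules(X, y, names, cfg):
    """Independent oracle: enumerate every non-empty antecedent and apply the
    support/confidence/length thresholds directly."""
    X = np.asarray(X, dtype=bool)
    y = np.asarray(y, dtype=bool)
    n, m = X.shape
    out = {}
    for r in range(1, min(cfg.max_length, m) + 1):
        for combo in itertools.combinations(range(m), r):
            mask = X[:, combo].all(axis=1)
            n_ante = int(mask.sum())
            n_ante_case = int((mask & y).sum())
            support = n_ante_case / n
            conf = n_ante_case / n_ante if n_ante else 0.0
            if support >= cfg.min_support - 1e-12 and \
                    conf >= cfg.min_confidence - 1e-12:
                out[tuple(names[j] for j in combo)] = (
                    n_ante, n_ante_case, support, conf)
    return out


class TestDownsampleBalance:
    def test_balanced_output_shape(self):
        rng = np.random.default_rng(0)
        X = rng.random((10_100, 3)) < 0.5
        y = np.r_[np.ones(100, dtype=bool), np.zeros(10_000, dtype=bool)]
        Xb, yb = sg.downsample_balance(X, y, seed=1)
        assert len(yb) == 200
        assert yb.sum() == 100

    def test_already_balanced_identity_up_to_order(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 2)) < 0.5
        y = np.r_[np.ones(20, dtype=bool), np.zeros(20, dtype=bool)]
        Xb, yb = sg.downsample_balance(X, y, seed=2)
        assert sorted(map(tuple, np.column_stack([Xb, yb]).tolist())) == \
            sorted(map(tuple, np.column_stack([X, y]).tolist()))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.random((500, 4)) < 0.3
        y = rng.random(500) < 0.1
        a = sg.downsample_balance(X, y, seed=7)
        b = sg.downsample_balance(X, y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_more_cases_than_controls_rejected(self):
        X = np.zeros((10, 1), dtype=bool)
        y = np.r_[np.ones(7, dtype=bool), np.zeros(3, dtype=bool)]
        with pytest.raises(ConfigError, match="balance"):
            sg.downsample_balance(X, y)


class TestAprioriRules:
    def test_perfect_predictor_confidence_one(self):
        n = 100
        y = np.r_[np.ones(50, dtype=bool), np.zeros(50, dtype=bool)]
        X = np.zeros((n, 2), dtype=bool)
        X[:40, 0] = True          # only cases carry the feature
        X[::3, 1] = True
        cfg = sg.AprioriConfig(min_support=0.05, min_confidence=0.55,
                               max_length=2)
        rules = sg.apriori_rules(X, y, ["a", "b"], cfg)
        ra = [r for r in rules if r.antecedent == ("a",)]
        assert len(ra) == 1 and ra[0].confidence == 1.0

    def test_infrequent_feature_and_supersets_absent(self):
        rng = np.random.default_rng(3)
        n = 400
        y = rng.random(n) < 0.5
        X = np.column_stack([rng.random(n) < 0.4,
                             np.zeros(n, dtype=bool)])
        X[:2, 1] = True  # feature below min support
        cfg = sg.AprioriConfig(min_support=0.05, min_confidence=0.1,
                               max_length=2)
        rules = sg.apriori_rules(X, y, ["a", "rare"], cfg)
        assert all("rare" not in r.antecedent for r in rules)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_8_features(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        X = rng.random((n, 8)) < rng.uniform(0.1, 0.6, size=8)
        y = rng.random(n) < 0.5
        cfg = sg.AprioriConfig(min_support=0.02, min_confidence=0.5,
                               max_length=8)
        rules = sg.apriori_rules(X, y, [f"f{j}" for j in range(8)], cfg)
        oracle = brute_force_rules(X, y, [f"f{j}" for j in range(8)], cfg)
        got = {r.antecedent: (r.n_antecedent, r.n_antecedent_cases,
                              r.support, r.confidence) for r in rules}
        assert set(got) == set(oracle)
        for k in got:
            assert got[k][0] == oracle[k][0]
            assert got[k][1] == oracle[k][1]
            assert got[k][2] == pytest.approx(oracle[k][2])
            assert got[k][3] == pytest.approx(oracle[k][3])

    def test_anti_monotone_subset_closure(self):
        rng = np.random.default_rng(4)
        n = 500
        X = rng.random((n, 6)) < 0.4
        y = rng.random(n) < 0.5
        cfg = sg.AprioriConfig(min_support=0.02, min_confidence=0.01,
                               max_length=6)
        min_count = int(np.ceil(cfg.min_support * n))
        rules = sg.apriori_rules(X, y, [f"f{j}" for j in range(6)], cfg)
        names = [f"f{j}" for j in range(6)]
        Xb = np.asarray(X, dtype=bool)
        for r in rules:
            for k in range(len(r.antecedent)):
                sub = r.antecedent[:k] + r.antecedent[k + 1:]
                if not sub:
                    continue
                cols = [names.index(f) for f in sub]
                cnt = (Xb[:, cols].all(axis=1) & y).sum()
                assert cnt >= min_count

    def test_non_binary_feature_rejected(self):
        X = np.array([[0.5], [1.0]])
        y = np.array([True, False])
        with pytest.raises(ConfigError, match="binary"):
            sg.apriori_rules(X, y, ["a"], sg.AprioriConfig())

    def test_closed_reduction_drops_same_support_subsets(self):
        # b occurs only with a: {b} and {a,b} describe the same case rows,
        # so the non-closed {b} is dropped while {a} (larger support) stays
        y = np.r_[np.ones(30, dtype=bool), np.zeros(30, dtype=bool)]
        a = np.zeros(60, dtype=bool); a[:20] = True
        b = np.zeros(60, dtype=bool); b[:10] = True
        X = np.column_stack([a, b])
        cfg = sg.AprioriConfig(min_support=0.05, min_confidence=0.5,
                               max_length=2)
        rules = sg.apriori_rules(X, y, ["a", "b"], cfg)
        kept = {r.antecedent for r in sg.closed_reduction(rules)}
        assert ("b",) not in kept
        assert ("a", "b") in kept and ("a",) in kept


class TestWestfallYoung:
    def _null_data(self, seed, n=200, m=6):
        rng = np.random.default_rng(seed)
        X = rng.random((n, m)) < 0.3
        y = np.r_[np.ones(n // 2, dtype=bool), np.zeros(n // 2, dtype=bool)]
        return X, rng.permutation(y)

    def test_alpha_zero_selects_nothing(self):
        X, y = self._null_data(0)
        cfg = sg.AprioriConfig(min_support=0.02, min_confidence=0.4,
                               max_length=2, fwer_alpha=0.0001)
        rules = sg.apriori_rules(X, y, [f"f{j}" for j in range(6)], cfg)
        out = sg.westfall_young(rules, X, y, cfg, n_perm=100, alpha=0.0,
                                seed=1)
        assert not any(r.selected for r in out)

    def test_adjusted_p_at_least_unadjusted(self):
        X, y = self._null_data(1)
        cfg = sg.AprioriConfig(min_support=0.02, min_confidence=0.4,
                               max_length=2)
        rules = sg.apriori_rules(X, y, [f"f{j}" for j in range(6)], cfg)
        out = sg.westfall_young(rules, X, y, cfg, n_perm=200, seed=2)
        # unadjusted permutation p for each rule, same permutation stream
        rng = np.random.default_rng(2)
        perms = [rng.permutation(y) for _ in range(200)]
        names = [f"f{j}" for j in range(6)]
        for r in out:
            cols = [names.index(f) for f in r.antecedent]
            mask = X[:, cols].all(axis=1)
            n1 = mask.sum()
            stats = [float(sg._chi2_stat((mask & yp).sum(), n1,
                                         yp.sum(), len(yp)))
                     for yp in perms]
            p_unadj = np.mean(np.asarray(stats) >= r.stat)
            assert r.wy_p >= p_unadj - 1e-12

    def test_n_perm_below_100_rejected(self):
        X, y = self._null_data(2)
        cfg = sg.AprioriConfig(min_support=0.02, min_confidence=0.4,
                               max_length=2)
        rules = sg.apriori_rules(X, y, [f"f{j}" for j in range(6)], cfg)
        with pytest.raises(ConfigError, match="n_perm"):
            sg.westfall_young(rules, X, y, cfg, n_perm=50)

    def test_empty_rule_list_empty_selection(self):
        X, y = self._null_data(3)
        cfg = sg.AprioriConfig(min_support=0.9, min_confidence=0.99,
                               max_length=2)
        rules = sg.apriori_rules(X, y, [f"f{j}" for j in range(6)], cfg)
        assert rules == []
        assert sg.westfall_young(rules, X, y, cfg, n_perm=100) == []

    def test_fixed_family_mode_agrees_on_strong_signal(self):
        rng = np.random.default_rng(5)
        n = 400
        y = np.r_[np.ones(n // 2, dtype=bool), np.zeros(n // 2, dtype=bool)]
        strong = np.zeros(n, dtype=bool)
        strong[:80] = True          # only cases: very strong rule
        X = np.column_stack([strong, rng.random(n) < 0.3])
        cfg = sg.AprioriConfig(min_support=0.02, min_confidence=0.5,
                               max_length=2)
        rules = sg.apriori_rules(X, y, ["s", "n"], cfg)
        strict = sg.westfall_young(rules, X, y, cfg, n_perm=200, seed=6)
        fixed = sg.westfall_young_fixed(rules, X, y, ["s", "n"], cfg,
                                        n_perm=200, seed=6)
        s1 = {r.antecedent for r in strict if r.selected}
        s2 = {r.antecedent for r in fixed if r.selected}
        assert ("s",) in s1 and ("s",) in s2


class TestSubgroupMetrics:
    def _rule(self, ante):
        return sg.SubgroupRule(antecedent=ante, support=0.1, confidence=0.6,
                               n_antecedent=10, n_antecedent_cases=6,
                               stat=1.0)

    def test_katz_ci_closed_form(self):
        # in-group 30/1000 cases vs out-group 10/1000
        X = np.zeros((2000, 1), dtype=bool)
        X[:1000, 0] = True
        y = np.zeros(2000, dtype=bool)
        y[:30] = True
        y[1000:1010] = True
        out = sg.subgroup_metrics(self._rule(("g",)), X, y, ["g"])
        assert out.risk_ratio == pytest.approx(3.0, abs=1e-12)
        se = np.sqrt(1 / 30 - 1 / 1000 + 1 / 10 - 1 / 1000)
        z = 1.959963984540054
        assert out.rr_ci_low == pytest.approx(3.0 * np.exp(-z * se), rel=1e-6)
        assert out.rr_ci_high == pytest.approx(3.0 * np.exp(z * se), rel=1e-6)
        assert out.prevalence == 0.5

    def test_everyone_in_group_flagged_undefined(self):
        X = np.ones((50, 1), dtype=bool)
        y = np.r_[np.ones(5, dtype=bool), np.zeros(45, dtype=bool)]
        out = sg.subgroup_metrics(self._rule(("g",)), X, y, ["g"])
        assert out.rr_flag == "undefined"
        assert np.isnan(out.risk_ratio)

    def test_zero_cell_continuity_corrected(self):
        X = np.zeros((200, 1), dtype=bool)
        X[:100, 0] = True
        y = np.zeros(200, dtype=bool)
        y[:5] = True  # no out-group cases
        out = sg.subgroup_metrics(self._rule(("g",)), X, y, ["g"])
        assert out.rr_flag == "continuity-corrected"
        assert np.isfinite(out.risk_ratio) and out.risk_ratio > 1

    def test_age_feature_cut(self):
        col, name = sg.make_age_feature([30, 35, 40], cut=35)
        assert col.tolist() == [False, True, True]
        assert name == "age_35plus"
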
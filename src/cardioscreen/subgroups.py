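"""High-risk subgroup discovery: Apriori rule mining with Westfall-Young
permutation control and full-data risk reporting.

The workflow mirrors subgroup discovery on claims covariates:

1. down-sample non-cases to a 50/50 class balance (all cases kept);
2. mine, level-wise with the Apriori anti-monotone pruning, every rule
   ``antecedent => outcome`` whose support (fraction of the balanced data
   with the antecedent AND the outcome) and confidence (fraction of
   antecedent holders with the outcome) clear the configured minima, with a
   bounded antecedent length -- maternal age enters as the binary feature
   "age >= 35";
3. control the family-wise error rate with Westfall-Young maxT permutation:
   the outcome labels are permuted, the rule family re-mined per permutation
   under identical thresholds, and each observed rule statistic compared to
   the permutation distribution of the family maximum;
4. report each selected subgroup's prevalence and risk ratio (Katz
   log-normal CI) in the full, un-downsampled data.

The per-rule association statistic is the Pearson chi-square of the rule's
2x2 table on balanced data (configurable to confidence ranking); an optional
closed-set reduction drops antecedents with a same-support superset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import ConfigError


@dataclass(frozen=True)
class AprioriConfig:
    min_support: float = 0.001
    min_confidence: float = 0.55
    max_length: int = 10
    n_permutations: int = 500
    fwer_alpha: float = 0.05
    statistic: str = "chi2"        # or "confidence"
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_support", "min_confidence", "fwer_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.max_length < 1:
            raise ConfigError(
                f"max_length must be >= 1, got {self.max_length}")
        if self.statistic not in ("chi2", "confidence"):
            raise ConfigError(f"unknown statistic {self.statistic!r}")


@dataclass
class SubgroupRule:
    """One mined rule: antecedent code-set => outcome."""

    antecedent: tuple[str, ...]
    support: float                 # P(antecedent & outcome), balanced data
    confidence: float              # P(outcome | antecedent), balanced data
    n_antecedent: int
    n_antecedent_cases: int
    stat: float
    wy_p: float = np.nan
    selected: bool = False
    prevalence: float = np.nan     # full-data
    risk_ratio: float = np.nan     # full-data
    rr_ci_low: float = np.nan
    rr_ci_high: float = np.nan
    rr_flag: str = ""


# --------------------------------------------------------------------------
# class-balance down-sampling
# --------------------------------------------------------------------------

def downsample_balance(X, y, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Keep all cases; sample non-cases without replacement to match.

    Deterministic under ``seed``.  Raises when cases outnumber non-cases
    (balance cannot be reached by down-sampling non-cases).
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(bool)
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ConfigError("need at least one case and one non-case")
    if n_case > n_ctrl:
        raise ConfigError(
            f"{n_case} cases exceed {n_ctrl} non-cases; cannot balance by "
            "down-sampling non-cases")
    rng = np.random.default_rng(seed)
    ctrl_idx = np.flatnonzero(~y)
    keep_ctrl = rng.choice(ctrl_idx, size=n_case, replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(y), keep_ctrl]))
    return X[idx], y[idx]


# --------------------------------------------------------------------------
# Apriori mining core
# --------------------------------------------------------------------------

def _chi2_stat(a, n1, n_case, n):
    """Pearson chi-square of the (antecedent x outcome) 2x2 table, vectorized."""
    a = np.asarray(a, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    b = n1 - a
    c = n_case - a
    d = n - n1 - c
    denom = n1 * (n - n1) * n_case * (n - n_case)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, stat, 0.0)


def _mine_counts(
    X: np.ndarray, y: np.ndarray, min_count: int, max_len: int
):
    """Level-wise frequent-antecedent generation.

    Support counting is restricted to case rows (support of ``A => y`` is
    anti-monotone in A there); total antecedent counts over all rows are
    carried along for confidence.  Yields (itemsets, case_counts, all_counts).
    """
    n, m = X.shape
    Xc = X[y]
    itemsets: list[tuple[int, ...]] = []
    case_counts: list[int] = []
    all_counts: list[int] = []

    cc = Xc.sum(axis=0)
    frequent = np.flatnonzero(cc >= min_count)
    level_sets = [(int(j),) for j in frequent]
    level_case = Xc[:, frequent]
    level_all = X[:, frequent]
    freq_set = set(level_sets)
    itemsets.extend(level_sets)
    case_counts.extend(int(v) for v in cc[frequent])
    all_counts.extend(int(v) for v in X[:, frequent].sum(axis=0))

    length = 1
    while level_sets and length < max_len:
        cand_sets: list[tuple[int, ...]] = []
        cand_cols: list[tuple[int, int]] = []  # (index in level, new item)
        for i in range(len(level_sets)):
            for j in range(i + 1, len(level_sets)):
                a, b = level_sets[i], level_sets[j]
                if a[:-1] != b[:-1]:
                    break  # sorted prefixes: no further joins for i
                cand = a + (b[-1],)
                # anti-monotone prune: every (l)-subset must be frequent
                if all(cand[:k] + cand[k + 1:] in freq_set
                       for k in range(len(cand))):
                    cand_sets.append(cand)
                    cand_cols.append((i, b[-1]))
        if not cand_sets:
            break
        new_sets, new_case, new_all = [], [], []
        for cand, (i, item) in zip(cand_sets, cand_cols):
            col_c = level_case[:, i] & Xc[:, item]
            cnt = int(col_c.sum())
            if cnt >= min_count:
                new_sets.append(cand)
                new_case.append(col_c)
                new_all.append(level_all[:, i] & X[:, item])
        if not new_sets:
            break
        level_sets = new_sets
        level_case = np.column_stack(new_case)
        level_all = np.column_stack(new_all)
        freq_set.update(new_sets)
        itemsets.extend(new_sets)
        case_counts.extend(int(c.sum()) for c in new_case)
        all_counts.extend(int(c.sum()) for c in new_all)
        length += 1

    return itemsets, np.array(case_counts, dtype=np.int64), \
        np.array(all_counts, dtype=np.int64)


def _mine_rule_arrays(X, y, cfg: AprioriConfig):
    """(itemsets, case_counts, all_counts, stats) for rules passing all
    thresholds."""
    n = len(y)
    n_case = int(y.sum())
    min_count = max(1, int(np.ceil(cfg.min_support * n - 1e-9)))
    itemsets, cc, ac = _mine_counts(X, y, min_count, cfg.max_length)
    if not itemsets:
        return [], np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(ac > 0, cc / ac, 0.0)
    keep = conf >= cfg.min_confidence
    itemsets = [s for s, k in zip(itemsets, keep) if k]
    cc, ac = cc[keep], ac[keep]
    if cfg.statistic == "chi2":
        stats = _chi2_stat(cc, ac, n_case, n)
    else:
        stats = np.where(ac > 0, cc / ac, 0.0)
    return itemsets, cc, ac, stats


def _check_binary(X) -> np.ndarray:
    X = np.asarray(X)
    if X.dtype != bool:
        vals = np.unique(X)
        if not np.isin(vals, (0, 1)).all():
            raise ConfigError("features must be binary (0/1)")
        X = X.astype(bool)
    return X


def apriori_rules(
    X, y, feature_names: list[str], cfg: AprioriConfig
) -> list[SubgroupRule]:
    """Every outcome-consequent rule meeting support/confidence/length bounds.

    ``X`` is the balanced binary feature matrix (including the dichotomized
    age feature), ``y`` the balanced outcome.  Antecedents are canonical
    (sorted feature order, no duplicates).
    """
    cfg.validate()
    X = _check_binary(X)
    y = np.asarray(y).astype(bool)
    n = len(y)
    itemsets, cc, ac, stats = _mine_rule_arrays(X, y, cfg)
    rules = []
    for s, a, t, st in zip(itemsets, cc, ac, stats):
        rules.append(SubgroupRule(
            antecedent=tuple(feature_names[j] for j in s),
            support=a / n,
            confidence=a / t if t else 0.0,
            n_antecedent=int(t),
            n_antecedent_cases=int(a),
            stat=float(st),
        ))
    rules.sort(key=lambda r: (len(r.antecedent), r.antecedent))
    return rules


def closed_reduction(rules: list[SubgroupRule]) -> list[SubgroupRule]:
    """Drop rules with a proper-superset antecedent of identical support.

    Such antecedents describe the same pregnancies as their closure; keeping
    only closed sets removes redundant rule listings.  Optional step,
    switchable in the pipeline.
    """
    by_count: dict[int, list[set]] = {}
    for r in rules:
        by_count.setdefault(r.n_antecedent_cases, []).append(set(r.antecedent))
    out = []
    for r in rules:
        a = set(r.antecedent)
        redundant = any(a < other for other in by_count[r.n_antecedent_cases])
        if not redundant:
            out.append(r)
    return out


# --------------------------------------------------------------------------
# Westfall-Young permutation FWER control
# --------------------------------------------------------------------------

def westfall_young(
    rules: list[SubgroupRule],
    X, y,
    cfg: AprioriConfig,
    n_perm: int | None = None,
    alpha: float | None = None,
    seed: int | None = None,
    refit_family: bool = True,
) -> list[SubgroupRule]:
    """maxT-adjusted p per rule; select at the family-wise error level.

    Per permutation the outcome labels are shuffled and -- in the strict
    construction (``refit_family=True``) -- the rule family is re-mined under
    identical thresholds; the maximum statistic over that family forms the
    reference distribution.  ``refit_family=False`` is the faster approximate
    mode that re-scores only the observed antecedents.  Adjusted p = fraction
    of permutations whose family maximum reaches the observed statistic.
    """
    cfg.validate()
    n_perm = cfg.n_permutations if n_perm is None else n_perm
    alpha = cfg.fwer_alpha if alpha is None else alpha
    seed = cfg.seed if seed is None else seed
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
    if not rules:
        return []
    X = _check_binary(X)
    y = np.asarray(y).astype(bool)
    n = len(y)
    rng = np.random.default_rng(seed)

    if not refit_family:
        raise ConfigError(
            "approximate (fixed-family) mode needs the feature-name order; "
            "call westfall_young_fixed instead")

    maxstats = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        _, _, _, stats = _mine_rule_arrays(X, yp, cfg)
        maxstats[b] = stats.max() if stats.size else 0.0

    out = []
    for r in rules:
        p = float(np.mean(maxstats >= r.stat))
        out.append(replace(r, wy_p=p, selected=bool(p <= alpha)))
    return out


def westfall_young_fixed(
    rules: list[SubgroupRule],
    X, y,
    feature_names: list[str],
    cfg: AprioriConfig,
    n_perm: int | None = None,
    alpha: float | None = None,
    seed: int | None = None,
) -> list[SubgroupRule]:
    """Approximate maxT: the observed rule family is held fixed and only
    re-scored under each permutation (no re-mining).  Faster; slightly
    anti-conservative relative to the strict construction."""
    cfg.validate()
    n_perm = cfg.n_permutations if n_perm is None else n_perm
    alpha = cfg.fwer_alpha if alpha is None else alpha
    seed = cfg.seed if seed is None else seed
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
    if not rules:
        return []
    X = _check_binary(X)
    y = np.asarray(y).astype(bool)
    n = len(y)
    col = {f: j for j, f in enumerate(feature_names)}
    masks = np.column_stack([
        X[:, [col[f] for f in r.antecedent]].all(axis=1) for r in rules])
    n1 = masks.sum(axis=0)
    rng = np.random.default_rng(seed)
    maxstats = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        a = masks[yp].sum(axis=0)
        if cfg.statistic == "chi2":
            stats = _chi2_stat(a, n1, int(y.sum()), n)
        else:
            stats = np.where(n1 > 0, a / n1, 0.0)
        maxstats[b] = stats.max() if stats.size else 0.0
    out = []
    for r in rules:
        p = float(np.mean(maxstats >= r.stat))
        out.append(replace(r, wy_p=p, selected=bool(p <= alpha)))
    return out


# --------------------------------------------------------------------------
# full-data reporting
# --------------------------------------------------------------------------

def subgroup_metrics(
    rule: SubgroupRule, X_full, y_full, feature_names: list[str],
) -> SubgroupRule:
    """Prevalence and risk ratio of the rule's subgroup in the full data.

    RR = risk(in-group) / risk(out-group) with the Katz log-normal 95% CI.
    A zero cell triggers the 0.5 continuity correction on all four cells
    (flagged); an empty in- or out-group leaves the RR undefined (flagged).
    """
    X_full = _check_binary(X_full)
    y_full = np.asarray(y_full).astype(bool)
    col = {f: j for j, f in enumerate(feature_names)}
    mask = X_full[:, [col[f] for f in rule.antecedent]].all(axis=1)
    n = len(y_full)
    n1 = int(mask.sum())
    n0 = n - n1
    prev = n1 / n
    if n1 == 0 or n0 == 0:
        return replace(rule, prevalence=prev, rr_flag="undefined")
    a = int((mask & y_full).sum())
    c = int((~mask & y_full).sum())
    flag = ""
    af, cf, n1f, n0f = float(a), float(c), float(n1), float(n0)
    if a == 0 or c == 0:
        af, cf, n1f, n0f = a + 0.5, c + 0.5, n1 + 1.0, n0 + 1.0
        flag = "continuity-corrected"
    rr = (af / n1f) / (cf / n0f)
    se = np.sqrt(1.0 / af - 1.0 / n1f + 1.0 / cf - 1.0 / n0f)
    z = 1.959963984540054
    return replace(rule, prevalence=prev, risk_ratio=float(rr),
                   rr_ci_low=float(rr * np.exp(-z * se)),
                   rr_ci_high=float(rr * np.exp(z * se)),
                   rr_flag=flag)


def make_age_feature(ages, cut: float = 35.0) -> tuple[np.ndarray, str]:
    """Dichotomized maternal age feature (age >= cut)."""
    return np.asarray(ages, dtype=float) >= cut, f"age_{int(cut)}plus"


def rules_table(rules: list[SubgroupRule]) -> pd.DataFrame:
    """Report rules in publication shape: antecedent labels, prevalence %,
    risk ratio with CI, WY-adjusted p."""
    rows = []
    for r in rules:
        ci = ("" if np.isnan(r.risk_ratio) else
              f"{r.risk_ratio:.2f} ({r.rr_ci_low:.2f}-{r.rr_ci_high:.2f})")
        rows.append({
            "rule": "; ".join(r.antecedent),
            "prevalence_pct": round(100.0 * r.prevalence, 1)
            if np.isfinite(r.prevalence) else np.nan,
            "risk_ratio_ci": ci,
            "support": r.support,
            "confidence": r.confidence,
            "stat": r.stat,
            "wy_p": r.wy_p,
            "selected": r.selected,
            "flag": r.rr_flag,
        })
    return pd.DataFrame(rows, columns=[
        "rule", "prevalence_pct", "risk_ratio_ci", "support", "confidence",
        "stat", "wy_p", "selected", "flag"])
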
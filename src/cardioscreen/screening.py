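"""Mass univariate logistic screening of codes against a binary outcome.

Each code indicator is screened in its own logistic model

    logit P(Y=1) = b0 + b1 * code + f(maternal age)

where f is a restricted cubic spline (4 knots at the 5/35/65/95th age
percentiles by default).  P-values come from the likelihood-ratio test of the
code term (1 df); selection is by Benjamini-Hochberg step-up at 1/5/10% FDR;
selected odds ratios are de-biased for the winner's curse with a conditional
bootstrap, and a signed -log10(p) column feeds signed Manhattan plots.

The inner fitter is a compact Newton (IRLS) solver so that the screening
loop -- codes x bootstrap resamples x simulation replicates -- carries no
per-fit overhead; its estimates agree with a conventional GLM fit to well
below reporting precision (asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .simulate import ConfigError

#: Display cap for -log10(p) in signed Manhattan output.
LOG10P_CAP = 20.0

#: Harrell's default knot placements (percentiles) for restricted cubic splines.
_KNOT_QUANTILES = {
    3: (10, 50, 90),
    4: (5, 35, 65, 95),
    5: (5, 27.5, 50, 72.5, 95),
    6: (5, 23, 41, 59, 77, 95),
    7: (2.5, 18.33, 34.17, 50, 65.83, 81.67, 97.5),
}


# --------------------------------------------------------------------------
# restricted cubic spline basis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineBasis:
    """Restricted cubic spline basis: linear tails, C2-continuous interior.

    For knots t_1 < ... < t_k the basis is x itself plus k-2 truncated-power
    terms, i.e. dimension k-1.
    """

    knots: tuple[float, ...]

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = np.asarray(self.knots)
        k = len(t)
        denom = (t[-1] - t[0]) ** 2
        cols = [x]
        cub = lambda u: np.maximum(u, 0.0) ** 3
        for j in range(k - 2):
            term = (
                cub(x - t[j])
                - cub(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + cub(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
            ) / denom
            cols.append(term)
        return np.column_stack(cols)


def rcs_basis(ages, n_knots: int = 4) -> tuple[SplineBasis, np.ndarray]:
    """Basis with knots at the standard quantiles, plus the design columns.

    Raises when the ages hold too few distinct values to place strictly
    increasing knots (use fewer knots).
    """
    ages = np.asarray(ages, dtype=float)
    if n_knots < 3:
        raise ConfigError(f"n_knots must be >= 3, got {n_knots}")
    if np.unique(ages).size < n_knots:
        raise ValueError(
            f"only {np.unique(ages).size} distinct age values for {n_knots} "
            "knots; use fewer knots")
    q = _KNOT_QUANTILES.get(n_knots, tuple(np.linspace(5, 95, n_knots)))
    knots = np.quantile(ages, np.asarray(q) / 100.0)
    if not np.all(np.diff(knots) > 0):
        raise ValueError(
            "age quantiles produce duplicated knots; use fewer knots")
    basis = SplineBasis(knots=tuple(knots))
    return basis, basis.transform(ages)


# --------------------------------------------------------------------------
# logistic fitting (Newton / IRLS)
# --------------------------------------------------------------------------

def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _fit_damped(
    X: np.ndarray, y: np.ndarray, beta0: np.ndarray,
    max_iter: int = 60, tol: float = 1e-10,
) -> tuple[np.ndarray, float, np.ndarray | None, bool]:
    """Robust damped-Newton fallback with step-halving on the likelihood."""
    n, p = X.shape
    beta = beta0.copy()
    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, ll, None, False
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = X @ cand
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-14:
                break
            t *= 0.5
        improve = ll_c - ll
        beta, eta, ll = cand, eta_c, ll_c
        if np.abs(beta).max() > 500.0:
            return beta, ll, None, False
        if improve < tol and np.abs(grad).max() < 1e-6 * n:
            converged = True
            break
    if not converged:
        mu = expit(eta)
        if np.abs(X.T @ (y - mu)).max() < 1e-6 * max(n, 100):
            converged = True
    if not converged:
        return beta, ll, None, False
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, ll, None, False
    return beta, ll, cov, True


def fit_logistic(
    X: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None,
    max_iter: int = 25, tol: float = 1e-9,
) -> tuple[np.ndarray, float, np.ndarray | None, bool]:
    """Maximum-likelihood logistic fit by Newton iteration.

    Returns (beta, loglik, covariance, converged).  Covariance is the inverse
    observed information; None when the information matrix is singular.
    Unbounded drift of a coefficient (|beta| > 500) is treated as
    separation/degeneracy (non-convergence); genuine separation of a binary
    code indicator is caught earlier from its empty 2x2 cell.

    The primary path is undamped Newton on the step-norm criterion (fast for
    the warm-started mass-screening loop); any sign of trouble falls back to
    a damped, likelihood-monotone solver.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    eye = 1e-12 * np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + eye, grad)
        except np.linalg.LinAlgError:
            break  # fall back to damped path
        beta = beta + step
        if np.abs(beta).max() > 500.0 or not np.all(np.isfinite(beta)):
            break
        if np.abs(step).max() < 1e-9:
            eta = X @ beta
            mu = expit(eta)
            w = mu * (1.0 - mu)
            H = (X * w[:, None]).T @ X
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                break
            return beta, _loglik(eta, y), cov, True
    start = np.zeros(p) if beta0 is None else beta0.astype(float)
    return _fit_damped(X, y, start)


# --------------------------------------------------------------------------
# per-code fits
# --------------------------------------------------------------------------

@dataclass
class CodeFit:
    """Association estimate for one code (status 'ok' or 'non-estimable')."""

    code: str
    n_exposed: int
    n_exposed_cases: int
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    lrt: float
    p: float
    status: str


@dataclass
class _ReducedFit:
    beta: np.ndarray
    loglik: float


def _fit_reduced(y: np.ndarray, age_design: np.ndarray | None) -> _ReducedFit:
    n = len(y)
    D = (np.ones((n, 1)) if age_design is None
         else np.column_stack([np.ones(n), age_design]))
    beta, ll, _, conv = fit_logistic(D, y)
    if not conv:
        raise RuntimeError("reduced (age-only) model failed to converge")
    return _ReducedFit(beta=beta, loglik=ll)


def fit_code_model(
    y, x, age_design=None, code: str = "", reduced: _ReducedFit | None = None,
) -> CodeFit:
    """Spline-adjusted logistic fit of one binary code indicator.

    The likelihood-ratio statistic compares against the reduced model without
    the code (1 df).  Codes with an empty cell in the exposure-outcome 2x2
    margin, or whose fit separates, are returned as ``non-estimable`` with
    p = 1 so they never enter selection or bias correction.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    n = len(y)
    n_exp = int(x.sum())
    n_exp_case = int((x * y).sum())
    n_case = int(y.sum())

    def dud(status: str) -> CodeFit:
        return CodeFit(code=code, n_exposed=n_exp, n_exposed_cases=n_exp_case,
                       log_or=np.nan, se=np.nan, ci_low=np.nan,
                       ci_high=np.nan, lrt=np.nan, p=1.0, status=status)

    # any empty 2x2 cell implies an infinite MLE for the code coefficient
    a = n_exp_case                       # exposed cases
    b = n_exp - n_exp_case               # exposed non-cases
    c = n_case - n_exp_case              # unexposed cases
    d = (n - n_exp) - c                  # unexposed non-cases
    if min(a, b, c, d) == 0:
        return dud("non-estimable")

    if reduced is None:
        reduced = _fit_reduced(y, age_design)
    if age_design is None:
        D = np.column_stack([np.ones(n), x])
        beta0 = np.array([reduced.beta[0], 0.0])
    else:
        D = np.column_stack([np.ones(n), x, age_design])
        beta0 = np.concatenate([[reduced.beta[0], 0.0], reduced.beta[1:]])
    beta, ll, cov, conv = fit_logistic(D, y, beta0=beta0)
    if not conv or cov is None or cov[1, 1] <= 0:
        return dud("non-estimable")
    log_or = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    lrt = max(0.0, 2.0 * (ll - reduced.loglik))
    p = float(stats.chi2.sf(lrt, df=1))
    z = stats.norm.ppf(0.975)
    return CodeFit(code=code, n_exposed=n_exp, n_exposed_cases=n_exp_case,
                   log_or=log_or, se=se, ci_low=log_or - z * se,
                   ci_high=log_or + z * se, lrt=lrt, p=p, status="ok")


def _fit_panel(indicators, codes, y, age_design,
               reduced: _ReducedFit) -> list[CodeFit]:
    """One CodeFit per panel column, reusing the reduced fit."""
    from scipy import sparse as sp
    dense = (indicators.toarray().astype(np.float64)
             if sp.issparse(indicators) else
             np.asarray(indicators, dtype=np.float64))
    return [
        fit_code_model(y, dense[:, j], age_design, code=codes[j],
                       reduced=reduced)
        for j in range(dense.shape[1])
    ]


# --------------------------------------------------------------------------
# Benjamini-Hochberg selection
# --------------------------------------------------------------------------

def bh_select(pvals, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH: (adjusted p, selected mask at FDR q)."""
    pvals = np.asarray(pvals, dtype=float)
    if not 0.0 < q < 1.0:
        raise ConfigError(f"FDR level q must be in (0, 1), got {q}")
    if pvals.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject


# --------------------------------------------------------------------------
# screening table
# --------------------------------------------------------------------------

def signed_log10(p, log_or, cap: float = LOG10P_CAP
                 ) -> tuple[np.ndarray, np.ndarray]:
    """-log10(p) signed by the log-OR; capped at ``cap`` with overflow flag.

    Zero log-OR yields 0; p = 0 (underflow) is capped and flagged.
    """
    p = np.asarray(p, dtype=float)
    log_or = np.asarray(log_or, dtype=float)
    with np.errstate(divide="ignore"):
        mag = -np.log10(p)
    overflow = ~np.isfinite(mag) | (mag > cap)
    mag = np.where(overflow, cap, mag)
    sign = np.sign(log_or)
    val = np.where(np.isnan(log_or), np.nan, mag * sign)
    return val, overflow


def build_screening_table(
    fits: list[CodeFit],
    codes_meta: pd.DataFrame | None = None,
    fdr_levels: tuple[float, ...] = (0.01, 0.05, 0.10),
) -> pd.DataFrame:
    """Assemble per-code fits into the screening table (one BH family).

    Columns include raw and BH-adjusted p, selection flags per FDR level,
    odds ratios with Wald 95% CI, and the signed -log10 p for Manhattan
    output.  Selection is nested across levels by construction of BH.
    """
    tab = pd.DataFrame([f.__dict__ for f in fits])
    if codes_meta is not None:
        tab = pd.concat(
            [codes_meta.reset_index(drop=True),
             tab.drop(columns="code").reset_index(drop=True)], axis=1)
    p_adj, _ = bh_select(tab["p"].to_numpy(), max(fdr_levels))
    tab["p_adj"] = p_adj
    for q in sorted(fdr_levels):
        tab[f"selected_fdr{int(round(q * 100)):02d}"] = tab["p_adj"] <= q
    tab["odds_ratio"] = np.exp(tab["log_or"])
    tab["or_ci_low"] = np.exp(tab["ci_low"])
    tab["or_ci_high"] = np.exp(tab["ci_high"])
    sv, of = signed_log10(tab["p"].to_numpy(), tab["log_or"].to_numpy())
    tab["signed_log10_p"] = sv
    tab["log10p_overflow"] = of
    return tab


def screen(
    panels,
    outcome: pd.Series,
    ages: pd.Series,
    n_knots: int = 4,
    fdr_levels: tuple[float, ...] = (0.01, 0.05, 0.10),
) -> pd.DataFrame:
    """Screen every code of one run's panels against one outcome.

    ``panels`` is a list of CovariatePanel-shaped objects (same role, e.g. a
    diagnosis panel and a medication panel); their codes form a single BH
    family, matching a per-run multiplicity correction.  ``outcome`` and
    ``ages`` are Series indexed by pregnancy id.
    """
    fits: list[CodeFit] = []
    metas = []
    for panel in panels:
        y = outcome.loc[panel.pregnancy_ids].to_numpy(dtype=float)
        age = ages.loc[panel.pregnancy_ids].to_numpy(dtype=float)
        _, design = rcs_basis(age, n_knots=n_knots)
        reduced = _fit_reduced(y, design)
        fits.extend(_fit_panel(panel.indicators,
                               panel.codes["code"].tolist(), y, design,
                               reduced))
        metas.append(panel.codes)
    meta = pd.concat(metas, ignore_index=True)
    return build_screening_table(fits, codes_meta=meta, fdr_levels=fdr_levels)


# --------------------------------------------------------------------------
# winner's-curse bias correction
# --------------------------------------------------------------------------

def winners_curse_correct(
    panels,
    outcome: pd.Series,
    ages: pd.Series,
    table: pd.DataFrame,
    q: float = 0.05,
    B: int = 200,
    seed: int = 0,
    n_knots: int = 4,
) -> pd.DataFrame:
    """Conditional-bootstrap correction of selected codes' log odds ratios.

    For each of B bootstrap resamples of pregnancies (with replacement) the
    whole screen -- fits plus BH selection at the analysis FDR -- is rerun.
    For an originally selected code c, the selection bias estimate is the
    mean, over resamples in which c was re-selected, of (bootstrap log-OR -
    full-data log-OR); the corrected estimate subtracts it.  Codes never
    re-selected carry a missing correction and are flagged.

    Adds columns ``log_or_corrected``, ``or_corrected``,
    ``correction_missing`` to a copy of ``table``.
    """
    if B < 50:
        raise ConfigError(
            f"B must be >= 50 for a stable bias estimate, got {B}")
    sel_col = f"selected_fdr{int(round(q * 100)):02d}"
    if sel_col not in table.columns:
        raise ConfigError(f"table has no selection column for q={q}")
    selected_idx = np.flatnonzero(table[sel_col].to_numpy())
    out = table.copy()
    out["log_or_corrected"] = np.nan
    out["correction_missing"] = False
    if selected_idx.size == 0:
        out["or_corrected"] = np.nan
        return out

    rng = np.random.default_rng(seed)
    # pre-extract aligned arrays per panel
    prepared = []
    for panel in panels:
        y = outcome.loc[panel.pregnancy_ids].to_numpy(dtype=float)
        age = ages.loc[panel.pregnancy_ids].to_numpy(dtype=float)
        X = panel.indicators.toarray().astype(np.float64)
        prepared.append((X, y, age))
    m = sum(X.shape[1] for X, _, _ in prepared)
    full_log_or = table["log_or"].to_numpy()

    sums = np.zeros(m)
    times_selected = np.zeros(m, dtype=np.int64)
    for _ in range(B):
        boot_p = np.full(m, 1.0)
        boot_lor = np.full(m, np.nan)
        pos = 0
        for X, y, age in prepared:
            n = len(y)
            idx = rng.integers(0, n, size=n)
            yb, ab, Xb = y[idx], age[idx], X[idx]
            _, design = rcs_basis(ab, n_knots=n_knots)
            reduced = _fit_reduced(yb, design)
            for j in range(X.shape[1]):
                f = fit_code_model(yb, Xb[:, j], design, reduced=reduced)
                boot_p[pos + j] = f.p
                boot_lor[pos + j] = f.log_or
            pos += X.shape[1]
        _, rej = bh_select(boot_p, q)
        hit = rej & np.isfinite(boot_lor)
        sums[hit] += boot_lor[hit] - full_log_or[hit]
        times_selected[hit] += 1

    for i in selected_idx:
        if times_selected[i] == 0:
            out.iloc[i, out.columns.get_loc("correction_missing")] = True
        else:
            bias = sums[i] / times_selected[i]
            out.iloc[i, out.columns.get_loc("log_or_corrected")] = (
                full_log_or[i] - bias)
    out["or_corrected"] = np.exp(out["log_or_corrected"])
    return out


# --------------------------------------------------------------------------
# maternal age-risk curve
# --------------------------------------------------------------------------

def age_risk_curve(
    y, ages, grid=None, n_knots: int = 4,
    bin_width: int = 2, min_bin_n: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted outcome risk across maternal age from an age-only spline fit.

    Returns ``(curve, bins)``: the spline-model predicted probability at each
    grid age (with an extrapolation flag outside the observed range) and the
    observed risk per ``bin_width``-year age bin, restricted to bins holding
    more than ``min_bin_n`` pregnancies.
    """
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    basis, design = rcs_basis(ages, n_knots=n_knots)
    n = len(y)
    D = np.column_stack([np.ones(n), design])
    beta, _, _, conv = fit_logistic(D, y)
    if not conv:
        raise RuntimeError("age-only model failed to converge")
    if grid is None:
        grid = np.arange(np.floor(ages.min()), np.ceil(ages.max()) + 1)
    grid = np.asarray(grid, dtype=float)
    G = np.column_stack([np.ones(len(grid)), basis.transform(grid)])
    risk = 1.0 / (1.0 + np.exp(-(G @ beta)))
    curve = pd.DataFrame({
        "age": grid,
        "risk": risk,
        "extrapolated": (grid < ages.min()) | (grid > ages.max()),
    })
    lo = np.floor(ages / bin_width) * bin_width
    binned = pd.DataFrame({"bin_lo": lo, "y": y}).groupby("bin_lo").agg(
        n=("y", "size"), risk=("y", "mean")).reset_index()
    binned["bin_mid"] = binned["bin_lo"] + bin_width / 2.0
    bins = binned[binned["n"] > min_bin_n].reset_index(drop=True)
    return curve, bins[["bin_lo", "bin_mid", "n", "risk"]]
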
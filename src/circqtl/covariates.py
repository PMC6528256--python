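"""Covariate modelling of circRNA expression.

Precision weights follow the voom recipe: the square-root residual standard
deviation from a per-feature least-squares fit is smoothed (lowess) against
mean log-count, and each observation receives the inverse fourth power of
the predicted square-root standard deviation at its fitted value. Weighted
least squares then drives covariate scans, covariate adjustment, repeated
random-subsampling differential expression, and the effect-size /
sample-size calculations for case-control power.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

LOWESS_FRAC = 0.5  # voom's published span


def build_design(covariates: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Numeric design matrix with intercept from a covariate table.

    Categorical (object/category) columns are dummy-coded dropping the first
    level; a RIN column automatically gains a RIN^2 companion. Aliased
    (linearly dependent) columns raise.
    """
    cov = covariates if columns is None else covariates[columns]
    parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for name in cov.columns:
        col = cov[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float))
            if name.upper() == "RIN":
                parts.append((col.astype(float) ** 2).rename(f"{name}2"))
    design = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        aliased = _aliased_columns(design.values)
        raise ValueError(
            f"rank-deficient design; aliased columns: {[design.columns[i] for i in aliased]}"
        )
    return design


def _aliased_columns(X: np.ndarray) -> list[int]:
    _, R = np.linalg.qr(X)
    return [i for i in range(X.shape[1]) if abs(R[i, i]) < 1e-10] or [X.shape[1] - 1]


def voom_weights(logcpm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Observation-level precision weights from the mean-variance trend.

    With a single feature (degenerate trend) all weights are 1.
    """
    X = design.values
    Y = logcpm.values
    n, p = X.shape[0], X.shape[1]
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    if np.linalg.matrix_rank(X) < p:
        aliased = _aliased_columns(X)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid = Y - fitted
    sd = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    sqrt_sd = np.sqrt(sd)
    mean_log = Y.mean(axis=1)
    if Y.shape[0] < 2:
        return pd.DataFrame(1.0, index=logcpm.index, columns=logcpm.columns)
    trend = lowess(sqrt_sd, mean_log, frac=LOWESS_FRAC, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # predict sqrt-sd at every fitted log-count, clamped to the trend range
    pred = np.interp(np.clip(fitted, tx[0], tx[-1]), tx, ty)
    pred = np.clip(pred, max(ty.min(), 1e-6), None)
    w = pred ** -4.0
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


def _wls_fit(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Weighted least squares for one feature; returns (beta, XtWX_inv, sigma2, df)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    XtX = Xw.T @ Xw
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    df = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    return beta, XtX_inv, sigma2, df


@dataclass
class DeResult:
    """Per-feature association with a covariate: coefficient (NaN for joint
    F-tests over multi-level factors), statistic, P and BH FDR."""

    table: pd.DataFrame  # index = feature; columns coef, stat, p, fdr
    covariate: str


def covariate_scan(
    expr: pd.DataFrame,
    weights: pd.DataFrame,
    design: pd.DataFrame,
    target_covariate: str | list[str],
) -> DeResult:
    """Weighted per-feature test of one covariate (t) or covariate set (F).

    ``target_covariate`` may name a single design column, a prefix matching
    a dummy-coded factor's columns, or an explicit list of columns. RIN and
    RIN^2 columns passed together are merged by min-P per feature before the
    BH correction, matching the merged reporting of the quadratic RIN term.
    Features with zero residual variance get P = 1.
    """
    targets = _resolve_targets(design, target_covariate)
    if _is_rin_pair(targets):
        res_parts = [
            _scan_columns(expr, weights, design, [t]).table for t in targets
        ]
        p = np.minimum(res_parts[0]["p"].values, res_parts[1]["p"].values)
        coef = np.where(
            res_parts[0]["p"].values <= res_parts[1]["p"].values,
            res_parts[0]["coef"].values,
            res_parts[1]["coef"].values,
        )
        stat = np.where(
            res_parts[0]["p"].values <= res_parts[1]["p"].values,
            res_parts[0]["stat"].values,
            res_parts[1]["stat"].values,
        )
        table = pd.DataFrame({"coef": coef, "stat": stat, "p": p}, index=expr.index)
        table["fdr"] = multipletests(table["p"].values, method="fdr_bh")[1]
        return DeResult(table=table, covariate="+".join(targets))
    res = _scan_columns(expr, weights, design, targets)
    return res


def _resolve_targets(design: pd.DataFrame, target) -> list[str]:
    if isinstance(target, (list, tuple)):
        cols = list(target)
    elif target in design.columns and f"{target}2" in design.columns and target.upper() == "RIN":
        cols = [target, f"{target}2"]  # quadratic companion rides along
    elif target in design.columns:
        cols = [target]
    else:
        cols = [c for c in design.columns if c.startswith(f"{target}_") or c in (target, f"{target}2")]
    missing = [c for c in cols if c not in design.columns]
    if missing or not cols:
        raise ValueError(f"target covariate {target!r} not found in design")
    return cols


def _is_rin_pair(targets: list[str]) -> bool:
    if len(targets) != 2:
        return False
    a, b = sorted(targets, key=len)
    return b == f"{a}2" and a.upper() == "RIN"


def _scan_columns(expr, weights, design, targets) -> DeResult:
    X = design.values
    idx = [design.columns.get_loc(c) for c in targets]
    keep = [i for i in range(X.shape[1]) if i not in idx]
    rows = []
    for i in range(expr.shape[0]):
        y = expr.values[i]
        w = weights.values[i]
        beta, XtX_inv, sigma2, df = _wls_fit(y, X, w)
        if not np.isfinite(sigma2) or sigma2 <= 1e-12:
            rows.append((np.nan, 0.0, 1.0))
            continue
        if len(idx) == 1:
            j = idx[0]
            se = np.sqrt(sigma2 * XtX_inv[j, j])
            t = beta[j] / se if se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t), df)
            rows.append((beta[j], t, min(p, 1.0)))
        else:
            # F-test: compare full vs reduced weighted fit
            _, _, sigma2_red, df_red = _wls_fit(y, X[:, keep], w)
            rss_full = sigma2 * df
            rss_red = sigma2_red * (df_red if df_red > 0 else df + len(idx))
            q = len(idx)
            F = ((rss_red - rss_full) / q) / (rss_full / df)
            p = stats.f.sf(max(F, 0.0), q, df)
            rows.append((np.nan, F, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["coef", "stat", "p"], index=expr.index)
    table["fdr"] = multipletests(table["p"].values, method="fdr_bh")[1]
    return DeResult(table=table, covariate="+".join(targets))


def adjust_covariates(
    expr: pd.DataFrame, weights: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Residuals of the per-feature weighted fit: covariate-adjusted expression."""
    X = design.values
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    out = np.empty_like(expr.values, dtype=float)
    for i in range(expr.shape[0]):
        w = weights.values[i]
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        beta, *_ = np.linalg.lstsq(Xw, expr.values[i] * sw, rcond=None)
        out[i] = expr.values[i] - X @ beta
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def random_sampling_de(
    expr: pd.DataFrame,
    weights: pd.DataFrame,
    covariates: pd.DataFrame,
    groups: pd.Series,
    group_sizes: tuple[int, int],
    n_reps: int,
    threshold: int,
    seed: int,
    fdr: float = 0.05,
) -> pd.Index:
    """Stable differential-expression calls under repeated random subsampling.

    Each repetition draws ``group_sizes`` samples from the two groups,
    re-runs the covariate scan on the group indicator, and a feature is
    reported only if it reaches FDR < ``fdr`` in strictly more than
    ``threshold`` repetitions.
    """
    rng = np.random.default_rng(seed)
    labels = groups.loc[expr.columns]
    lev = sorted(labels.unique())
    if len(lev) != 2:
        raise ValueError("groups must have exactly two levels")
    ia = np.flatnonzero(labels.values == lev[0])
    ib = np.flatnonzero(labels.values == lev[1])
    na, nb = group_sizes
    if na > len(ia) or nb > len(ib):
        raise ValueError("requested group size exceeds available samples")
    hits = np.zeros(expr.shape[0], dtype=int)
    for _ in range(n_reps):
        sel = np.concatenate([rng.choice(ia, na, replace=False), rng.choice(ib, nb, replace=False)])
        sub_expr = expr.iloc[:, sel]
        sub_w = weights.iloc[:, sel]
        sub_cov = covariates.iloc[sel].copy()
        sub_cov["__group__"] = labels.values[sel]
        design = build_design(sub_cov)
        res = covariate_scan(sub_expr, sub_w, design, "__group__")
        hits += (res.table["fdr"].values < fdr).astype(int)
    return expr.index[hits > threshold]


def effect_size(expr_a: np.ndarray, expr_b: np.ndarray) -> float:
    """Standardized effect size |log2(fold change)| / sd.

    The fold change is the ratio of linear-scale group means; sd is the
    standard deviation of the pooled log2-scale expression of all samples.
    Inputs are log2-scale expression vectors.
    """
    a = np.asarray(expr_a, float)
    b = np.asarray(expr_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    sd = np.concatenate([a, b]).std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: effect size undefined")
    fc = (2.0 ** a).mean() / (2.0 ** b).mean()
    return abs(np.log2(fc)) / sd


def ttest_power(d: float, n: int, alpha: float) -> float:
    """Power of the two-sided two-sample t-test at per-group size n."""
    df = 2 * n - 2
    if df < 1:
        return 0.0
    nc = d * np.sqrt(n / 2.0)
    tcrit = stats.t.isf(alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest per-group n for the two-sided two-sample t-test to reach
    the target power at effect size d (noncentral-t power function)."""
    if d <= 0:
        raise ValueError("d must be > 0 (n would be infinite)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    lo, hi = 2, 4
    while ttest_power(d, hi, alpha) < power:
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("required sample size exceeds 1e7")
    while lo < hi:
        mid = (lo + hi) // 2
        if ttest_power(d, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo
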
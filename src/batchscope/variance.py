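"""Per-probe nested variance-component estimation.

Each probe is modelled on the log2 scale as

    y_j = mu + (fixed group effect) + sum_l b_{unit(j,l)} + eps_j

with the batch levels l (outermost to innermost, e.g. experiment > run >
chip) as independent Gaussian random effects and the biological variable, if
any, as a fixed effect.  Two estimators are provided:

* :func:`fit_nested_mom` -- the classical expected-mean-squares (ANOVA)
  estimator for balanced designs, vectorised across probes.  It solves the
  triangular EMS system linking stratum mean squares to variance components.
* :func:`fit_nested_reml` -- restricted maximum likelihood over nonnegative
  components.  On balanced designs the stratum sums of squares are sufficient
  and the optimisation runs on them directly (where the EMS solution, when
  interior, is the exact REML optimum); otherwise a dense-matrix likelihood
  is maximised.

Components are reported on the SD scale throughout, matching how relative
contributions are summarised (percent of the summed mean SD per level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datamodel import BATCH_LEVELS, DataError, ExpressionMatrix, SampleSheet

RESIDUAL = "residual"


class UnbalancedDesignError(DataError):
    """Raised by the EMS estimator on unbalanced designs."""


@dataclass(frozen=True)
class NestedModelSpec:
    """Fixed biological factor (or None) plus ordered nested random levels."""

    random_levels: tuple[str, ...]
    fixed_factor: str | None = None

    def __post_init__(self) -> None:
        order = [l for l in BATCH_LEVELS if l in self.random_levels]
        if list(self.random_levels) != order:
            raise DataError(
                f"random_levels must follow the nesting order {BATCH_LEVELS}"
            )
        if self.fixed_factor in self.random_levels:
            raise DataError("fixed_factor cannot also be a random level")


@dataclass
class NestedFit:
    """Variance-component estimates for one probe (SD scale).

    ``variances_raw`` keeps the signed EMS solutions (before truncation at
    zero); inestimable components (a level with a single unit) are NaN.
    """

    sds: dict[str, float]
    variances_raw: dict[str, float]
    converged: bool = True
    fixed_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class VarianceDecomposition:
    """Per-probe SDs plus cross-probe summaries.

    ``mean_sd`` averages the per-probe SD estimates per level (the quantity
    behind percent contributions); ``pooled_sd`` aggregates variance across
    probes before taking the square root, which is the estimator to use when
    checking recovery of generative SDs (per-probe SDs at few degrees of
    freedom are biased low by Jensen's inequality).
    """

    per_probe: pd.DataFrame
    mean_sd: pd.Series
    percent: pd.Series
    pooled_sd: pd.Series
    fixed_effects: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        total = float(self.percent.sum())
        if abs(total - 100.0) > 1e-9 and not self.percent.isna().any():
            raise DataError(f"percent contributions sum to {total}, expected 100")


# ---------------------------------------------------------------------------
# design analysis helpers
# ---------------------------------------------------------------------------

def _design_frame(sheet: SampleSheet, spec: NestedModelSpec,
                  sample_ids: Sequence[str]) -> pd.DataFrame:
    df = sheet.aligned_to(sample_ids)
    for lvl in spec.random_levels:
        if lvl not in df.columns:
            raise DataError(f"sample sheet lacks level column {lvl!r}")
    if spec.fixed_factor is not None and spec.fixed_factor not in df.columns:
        raise DataError(f"sample sheet lacks fixed factor {spec.fixed_factor!r}")
    return df


def _unit_codes(df: pd.DataFrame, levels: Sequence[str]) -> list[np.ndarray]:
    """Integer unit codes per level, in first-appearance order."""
    codes = []
    for lvl in levels:
        c = pd.Categorical(df[lvl], categories=df[lvl].drop_duplicates()).codes
        codes.append(np.asarray(c))
    return codes


def _is_balanced(df: pd.DataFrame, spec: NestedModelSpec) -> bool:
    levels = list(spec.random_levels)
    prev = pd.Series("all", index=df.index)
    for lvl in levels:
        kids = df.groupby(prev, sort=False)[lvl].nunique()
        if kids.nunique() > 1:
            return False
        sizes = df.groupby(df[lvl], sort=False).size()
        if sizes.nunique() > 1:
            return False
        prev = df[lvl]
    if spec.fixed_factor is not None:
        fx = df[spec.fixed_factor]
        if fx.isna().any():
            return False
        for lvl in levels:
            tab = pd.crosstab(df[lvl], fx)
            if len(np.unique(tab.to_numpy())) > 1:
                return False
    return True


# ---------------------------------------------------------------------------
# balanced-stratum machinery
# ---------------------------------------------------------------------------

@dataclass
class _Strata:
    levels: list[str]          # random levels with >1 unit, outer to inner
    dropped: list[str]         # levels with a single unit (inestimable)
    df: np.ndarray             # stratum dfs, one per level + residual last
    coef: np.ndarray           # EMS coefficients: w = coef @ sigma2
    ss: np.ndarray             # stratum sums of squares, (P, L+1)
    n: int
    fixed_effects: pd.DataFrame | None


def _stratum_ss(y: np.ndarray, df_design: pd.DataFrame,
                spec: NestedModelSpec) -> _Strata:
    """Stratum SS/df and EMS coefficients for a balanced design.

    ``y`` is (P, N).  With a fixed factor, samples are centred per factor
    level first and the residual df reduced accordingly (the factor is
    balanced across every batch unit, so it is orthogonal to the strata).
    """
    P, N = y.shape
    fixed_effects = None
    if spec.fixed_factor is not None:
        fx = pd.Categorical(df_design[spec.fixed_factor])
        groups = list(fx.categories)
        means = np.stack(
            [y[:, fx.codes == k].mean(axis=1) for k in range(len(groups))], axis=1
        )
        y = y - means[:, fx.codes]
        fixed_effects = pd.DataFrame(means, columns=groups)
        df_fixed = len(groups) - 1
    else:
        df_fixed = 0

    levels, dropped = [], []
    for lvl in spec.random_levels:
        if df_design[lvl].nunique() > 1:
            levels.append(lvl)
        else:
            dropped.append(lvl)

    codes = _unit_codes(df_design, levels)
    ss_list, dfs, n_units = [], [], []
    prev_means = y.mean(axis=1, keepdims=True)  # grand mean per probe
    prev_units = 1
    prev_codes = np.zeros(N, dtype=int)
    for lvl, code in zip(levels, codes):
        U = code.max() + 1
        counts = np.bincount(code, minlength=U)
        means = np.stack(
            [y[:, code == u].mean(axis=1) for u in range(U)], axis=1
        )
        # parent of each unit
        parent = np.empty(U, dtype=int)
        for u in range(U):
            parent[u] = prev_codes[code == u][0]
        dev = means - (prev_means if prev_units == 1 else prev_means[:, parent])
        ss_list.append((counts * dev**2).sum(axis=1))
        dfs.append(U - prev_units)
        n_units.append(U)
        prev_means, prev_units, prev_codes = means, U, code
    resid = y - prev_means[:, prev_codes] if levels else y - prev_means
    ss_list.append((resid**2).sum(axis=1))
    dfs.append(N - prev_units - df_fixed)

    L = len(levels)
    coef = np.zeros((L + 1, L + 1))
    m = [N // u for u in n_units] + [1]  # samples per unit, residual = 1
    for i in range(L + 1):
        for k in range(i, L + 1):
            coef[i, k] = m[k]
    return _Strata(
        levels=levels,
        dropped=dropped,
        df=np.asarray(dfs, dtype=float),
        coef=coef,
        ss=np.stack(ss_list, axis=1),
        n=N,
        fixed_effects=fixed_effects,
    )


def _reml_from_strata(ss: np.ndarray, dfs: np.ndarray, coef: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 200
                      ) -> tuple[np.ndarray, bool]:
    """Maximise the balanced REML likelihood for one probe's stratum SS."""
    ms = ss / dfs
    start = np.linalg.solve(coef, ms)
    if (start > 0).all():
        # interior EMS solution solves the REML equations exactly
        return start, True
    start = np.maximum(start, 1e-8)

    def nll(s2: np.ndarray) -> float:
        w = coef @ s2
        if (w <= 0).any():
            return np.inf
        return 0.5 * float((dfs * np.log(w) + ss / w).sum())

    def grad(s2: np.ndarray) -> np.ndarray:
        w = coef @ s2
        return coef.T @ (0.5 * (dfs / w - ss / w**2))

    bounds = [(0.0, None)] * (len(start) - 1) + [(1e-12, None)]
    res = minimize(
        nll, start, jac=grad, method="L-BFGS-B", bounds=bounds,
        options=dict(ftol=tol * 1e-4, gtol=1e-10, maxiter=max_iter),
    )
    return res.x, bool(res.success)


# ---------------------------------------------------------------------------
# public estimators
# ---------------------------------------------------------------------------

def _as_matrix(y: np.ndarray | Sequence[float]) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def fit_nested_mom(
    y: np.ndarray | Sequence[float],
    sheet: SampleSheet,
    spec: NestedModelSpec,
) -> NestedFit | list[NestedFit]:
    """Expected-mean-squares estimator on a balanced design.

    ``y`` is one probe's values (aligned with the sheet's row order) or a
    (probes x samples) matrix.  Negative EMS solutions are truncated to zero
    for the reported SDs; the signed solutions are kept in
    ``variances_raw``.
    """
    arr = _as_matrix(y)
    df_design = sheet.frame
    if arr.shape[1] != len(df_design):
        raise DataError(
            f"y has {arr.shape[1]} samples but the sheet has {len(df_design)}"
        )
    if not _is_balanced(df_design, spec):
        raise UnbalancedDesignError(
            "design is unbalanced (unequal children counts or a fixed factor "
            "not balanced across batch units); use fit_nested_reml instead"
        )
    strata = _stratum_ss(arr, df_design, spec)
    ms = strata.ss / strata.df
    raw = np.linalg.solve(strata.coef, ms.T).T  # (P, L+1)
    trunc = np.maximum(raw, 0.0)
    fits = []
    for p in range(arr.shape[0]):
        names = strata.levels + [RESIDUAL]
        sds = {n: float(np.sqrt(v)) for n, v in zip(names, trunc[p])}
        raw_d = {n: float(v) for n, v in zip(names, raw[p])}
        for lvl in strata.dropped:
            sds[lvl] = float("nan")
            raw_d[lvl] = float("nan")
        fx = {}
        if strata.fixed_effects is not None:
            fx = {c: float(strata.fixed_effects.iloc[p][c])
                  for c in strata.fixed_effects.columns}
        fits.append(NestedFit(sds=sds, variances_raw=raw_d, fixed_effects=fx))
    return fits[0] if np.asarray(y).ndim == 1 else fits


def _dense_reml(
    yv: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """General REML for one probe: returns (variances, beta, converged)."""
    n = len(yv)
    Gs = [Z @ Z.T for Z in Zs] + [np.eye(n)]
    k = len(Gs)
    total = float(np.var(yv, ddof=1)) if n > 1 else 0.0
    start = np.full(k, max(total / k, 1e-6))

    def neg2(s2: np.ndarray):
        V = sum(s * G for s, G in zip(s2, Gs))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(k)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, np.zeros(k)
        P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
        Py = P @ yv
        val = logdet + logdet_x + float(yv @ Py)
        g = np.array([float(np.trace(P @ G) - Py @ G @ Py) for G in Gs])
        return val, g

    res = minimize(
        lambda s: neg2(s)[0], start, jac=lambda s: neg2(s)[1],
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (k - 1) + [(1e-12, None)],
        options=dict(ftol=tol * 1e-2, gtol=1e-8, maxiter=max_iter),
    )
    s2 = res.x
    V = sum(s * G for s, G in zip(s2, Gs))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
    return s2, beta, bool(res.success)


def fit_nested_reml(
    y: np.ndarray | Sequence[float],
    sheet: SampleSheet,
    spec: NestedModelSpec,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> NestedFit:
    """REML estimate of the nested variance components for one probe."""
    yv = np.asarray(y, dtype=float)
    if yv.ndim != 1:
        raise DataError("fit_nested_reml takes one probe's values; see decompose")
    df_design = sheet.frame
    if len(yv) != len(df_design):
        raise DataError("y length does not match the sample sheet")

    if np.ptp(yv) == 0.0:
        sds = {lvl: 0.0 for lvl in spec.random_levels}
        sds[RESIDUAL] = 0.0
        return NestedFit(sds=sds, variances_raw={k: 0.0 for k in sds},
                         converged=True)

    if _is_balanced(df_design, spec):
        strata = _stratum_ss(yv[None, :], df_design, spec)
        s2, ok = _reml_from_strata(
            strata.ss[0], strata.df, strata.coef, tol=tol, max_iter=max_iter
        )
        names = strata.levels + [RESIDUAL]
        sds = {n_: float(np.sqrt(max(v, 0.0))) for n_, v in zip(names, s2)}
        raw = {n_: float(v) for n_, v in zip(names, s2)}
        for lvl in strata.dropped:
            sds[lvl] = float("nan")
            raw[lvl] = float("nan")
        fx = {}
        if strata.fixed_effects is not None:
            fx = {c: float(strata.fixed_effects.iloc[0][c])
                  for c in strata.fixed_effects.columns}
        return NestedFit(sds=sds, variances_raw=raw, converged=ok,
                         fixed_effects=fx)

    # general path: dense REML
    levels = [l for l in spec.random_levels if df_design[l].nunique() > 1]
    dropped = [l for l in spec.random_levels if l not in levels]
    codes = _unit_codes(df_design, levels)
    n = len(yv)
    Zs = []
    for code in codes:
        U = code.max() + 1
        Z = np.zeros((n, U))
        Z[np.arange(n), code] = 1.0
        Zs.append(Z)
    if spec.fixed_factor is not None:
        fx_cat = pd.Categorical(df_design[spec.fixed_factor])
        X = np.zeros((n, len(fx_cat.categories)))
        X[np.arange(n), fx_cat.codes] = 1.0  # cell-means coding
    else:
        X = np.ones((n, 1))
    s2, beta, ok = _dense_reml(yv, X, Zs, tol, max_iter)
    names = levels + [RESIDUAL]
    sds = {n_: float(np.sqrt(max(v, 0.0))) for n_, v in zip(names, s2)}
    raw = {n_: float(v) for n_, v in zip(names, s2)}
    for lvl in dropped:
        sds[lvl] = float("nan")
        raw[lvl] = float("nan")
    fx = {}
    if spec.fixed_factor is not None:
        fx = {c: float(b) for c, b in zip(fx_cat.categories, beta)}
    return NestedFit(sds=sds, variances_raw=raw, converged=ok, fixed_effects=fx)


def decompose(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    spec: NestedModelSpec,
    estimator: str = "reml",
) -> VarianceDecomposition:
    """Probe-wise variance decomposition with cross-probe summaries.

    Probes with zero variance are flagged and skipped rather than fitted;
    per-probe failures never abort the batch.  ``estimator`` may be "reml"
    (default) or "mom" (balanced designs only, much faster).
    """
    sheet_aligned = SampleSheet(sheet.aligned_to(m.sample_ids))
    x = m.values.to_numpy()
    levels = list(spec.random_levels) + [RESIDUAL]

    rows: list[dict] = []
    fx_rows: list[dict] = []
    if estimator == "mom":
        fits = fit_nested_mom(x, sheet_aligned, spec)
        for pid, fit in zip(m.probe_ids, fits):
            rows.append({"probe_id": pid, "converged": fit.converged,
                         **{l: fit.sds.get(l, np.nan) for l in levels}})
            fx_rows.append({"probe_id": pid, **fit.fixed_effects})
    elif estimator == "reml":
        for pid, yv in zip(m.probe_ids, x):
            if np.ptp(yv) == 0.0:
                rows.append({"probe_id": pid, "converged": False,
                             **{l: np.nan for l in levels}})
                fx_rows.append({"probe_id": pid})
                continue
            try:
                fit = fit_nested_reml(yv, sheet_aligned, spec)
            except Exception:
                rows.append({"probe_id": pid, "converged": False,
                             **{l: np.nan for l in levels}})
                fx_rows.append({"probe_id": pid})
                continue
            rows.append({"probe_id": pid, "converged": fit.converged,
                         **{l: fit.sds.get(l, np.nan) for l in levels}})
            fx_rows.append({"probe_id": pid, **fit.fixed_effects})
    else:
        raise DataError(f"unknown estimator {estimator!r}; use 'reml' or 'mom'")

    per_probe = pd.DataFrame(rows).set_index("probe_id")
    est_levels = [l for l in levels if not per_probe[l].isna().all()]
    mean_sd = per_probe[est_levels].mean()
    percent = 100.0 * mean_sd / mean_sd.sum()

    # pooled recovery estimator: aggregate variance across probes, sqrt last
    try:
        if _is_balanced(sheet_aligned.frame, spec):
            strata = _stratum_ss(x, sheet_aligned.frame, spec)
            ms_pooled = strata.ss.sum(axis=0) / (strata.df * x.shape[0])
            v_pooled = np.maximum(np.linalg.solve(strata.coef, ms_pooled), 0.0)
            pooled = pd.Series(
                np.sqrt(v_pooled), index=strata.levels + [RESIDUAL]
            ).reindex(est_levels)
        else:
            raise UnbalancedDesignError("fall back to mean of fitted variances")
    except DataError:
        sd2 = per_probe[est_levels] ** 2
        pooled = np.sqrt(sd2.mean())

    fixed = pd.DataFrame(fx_rows).set_index("probe_id")
    return VarianceDecomposition(
        per_probe=per_probe,
        mean_sd=mean_sd,
        percent=percent,
        pooled_sd=pooled,
        fixed_effects=fixed if fixed.shape[1] else None,
    )
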
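"""Probe-wise batch correction.

The empirical-Bayes location/scale method proceeds in three stages:

1. *Standardisation* -- per probe, fit a least-squares location model
   (grand mean + optional covariates + batch terms constrained so the
   batch-size-weighted sum of batch effects is zero), pool a residual SD
   sigma_g over all samples, and standardise to z-scores.
2. *Method-of-moments hyperpriors* -- per batch i, the per-probe sample
   means gamma_hat_ig and sample variances delta_hat^2_ig of z feed
   cross-probe moment estimates: a Normal(gamma_bar_i, tau_bar^2_i) prior
   for the additive term and an InverseGamma(lambda_i, theta_i) prior for
   the multiplicative term (matching the inverse-gamma mean
   theta/(lambda-1) and variance theta^2/((lambda-1)^2 (lambda-2))).
3. *Posterior expectation* -- iterate the conditional posterior means

       gamma* = (n_i tau^2 gamma_hat + delta*^2 gamma_bar) / (n_i tau^2 + delta*^2)
       delta*^2 = (theta + 0.5 sum_j (z - gamma*)^2) / (n_i/2 + lambda - 1)

   to convergence; the adjusted value is
   sigma_g / delta*_ig * (z_gj - gamma*_ig) + stand_mean_gj.

A plain mean-centring baseline (subtract batch mean, add grand mean, per
probe) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DataError, ExpressionMatrix, SampleSheet


class ConfoundingError(DataError):
    """Batch fully confounded with a covariate: correction would erase biology."""


def invgamma_match(mean: float, var: float) -> tuple[float, float]:
    """Inverse-gamma (shape lambda, scale theta) matching a given mean and
    variance: mean = theta/(lambda-1), var = theta^2/((lambda-1)^2 (lambda-2))."""
    if var <= 0:
        raise DataError("variance must be positive to match an inverse gamma")
    lam = 2.0 + mean**2 / var
    theta = mean * (lam - 1.0)
    return lam, theta


@dataclass
class BatchCorrectionModel:
    """Fitted standardisation and per-batch adjustment parameters."""

    batch_level: str
    covariates: tuple[str, ...]
    alpha: pd.Series                   # per-probe grand location
    sigma: pd.Series                   # per-probe pooled SD
    stand_mean: pd.DataFrame           # probes x samples: alpha + covariate fit
    batch_of: pd.Series                # sample -> batch label
    batch_sizes: pd.Series             # batch -> n_i
    gamma_hat: pd.DataFrame            # batches x probes, raw additive
    delta_hat_sq: pd.DataFrame         # batches x probes, raw scale
    gamma_star: pd.DataFrame           # batches x probes, shrunken additive
    delta_star_sq: pd.DataFrame        # batches x probes, shrunken scale
    hyper: pd.DataFrame                # per batch: gamma_bar, tau_bar_sq, lambda_, theta
    n_iter: dict[str, int] | None = None
    passthrough_probes: tuple[str, ...] = ()  # zero residual variance: left as-is


def _design(sheet_df: pd.DataFrame, batch_level: str,
            covariates: Sequence[str]) -> tuple[pd.Categorical, np.ndarray]:
    batches = pd.Categorical(sheet_df[batch_level],
                             categories=sheet_df[batch_level].drop_duplicates())
    n = len(sheet_df)
    cov_cols = []
    for cov in covariates:
        if cov not in sheet_df.columns:
            raise DataError(f"unknown covariate column {cov!r}")
        # samples without a covariate value (e.g. controls without a
        # biological group) form their own level
        vals = sheet_df[cov].fillna("(none)")
        cat = pd.Categorical(vals)
        for k, lev in enumerate(cat.categories[1:], start=1):
            col = (cat.codes == k).astype(float)
            cov_cols.append(col)
    B = np.zeros((n, len(batches.categories)))
    B[np.arange(n), batches.codes] = 1.0
    X = np.column_stack([B] + cov_cols) if cov_cols else B
    expected_rank = B.shape[1] + len(cov_cols)
    if np.linalg.matrix_rank(X) < expected_rank:
        raise ConfoundingError(
            f"batch level {batch_level!r} is confounded with covariates "
            f"{tuple(covariates)}; correction would remove the biological signal"
        )
    return batches, X


def combat_fit(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    batch_level: str,
    covariates: Sequence[str] = (),
    conv: float = 1e-6,
    max_iter: int = 100,
) -> BatchCorrectionModel:
    """Fit the three-stage empirical-Bayes batch model."""
    df = sheet.aligned_to(m.sample_ids)
    y = m.values.to_numpy()  # (G, N)
    G, N = y.shape

    counts = df[batch_level].value_counts()
    if len(counts) < 2:
        raise DataError("need at least two batches to correct")
    small = counts[counts < 2]
    if len(small):
        raise DataError(
            f"batch(es) with a single sample cannot be corrected: "
            f"{small.index.tolist()}"
        )
    batches, X = _design(df, batch_level, covariates)
    nb = len(batches.categories)
    n_i = np.bincount(batches.codes, minlength=nb).astype(float)

    # stage 1: standardise
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (p, G)
    batch_coef = beta[:nb]                           # (nb, G)
    alpha = (n_i / N) @ batch_coef                   # (G,)
    cov_fit = (X[:, nb:] @ beta[nb:]).T if X.shape[1] > nb else np.zeros((G, N))
    fitted = (X @ beta).T                            # (G, N)
    resid = y - fitted
    sigma_sq = (resid**2).mean(axis=1)               # pooled over N, as a scale
    # probes with no residual variance (e.g. rank-stable probes after
    # quantile normalisation) cannot be standardised; they pass through
    flat = sigma_sq <= 0
    passthrough = tuple(p for p, f in zip(m.probe_ids, flat) if f)
    sigma_sq = np.where(flat, 1.0, sigma_sq)
    sigma = np.sqrt(sigma_sq)
    stand_mean = alpha[:, None] + cov_fit            # (G, N)
    z = (y - stand_mean) / sigma[:, None]

    # stage 2: per-batch raw estimates and cross-probe hyperpriors
    gamma_hat = np.empty((nb, G))
    delta_hat = np.empty((nb, G))
    for i in range(nb):
        zi = z[:, batches.codes == i]
        gamma_hat[i] = zi.mean(axis=1)
        delta_hat[i] = zi.var(axis=1, ddof=1)
    good = ~flat
    if good.sum() < 2:
        raise DataError("too few probes with residual variance to fit priors")
    gamma_bar = gamma_hat[:, good].mean(axis=1)
    tau_sq = gamma_hat[:, good].var(axis=1, ddof=1)
    d_mean = delta_hat[:, good].mean(axis=1)
    d_var = delta_hat[:, good].var(axis=1, ddof=1)
    if (tau_sq <= 0).any() or (d_var <= 0).any():
        raise DataError(
            "degenerate hyperpriors: cross-probe variance of the batch "
            "estimates is zero (too few probes or constant data); "
            f"tau^2={tau_sq.tolist()}, var(delta^2)={d_var.tolist()}"
        )
    lam_theta = [invgamma_match(mu, v) for mu, v in zip(d_mean, d_var)]
    lam = np.array([lt[0] for lt in lam_theta])
    theta = np.array([lt[1] for lt in lam_theta])

    # stage 3: iterate conditional posterior means
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    iters: dict[str, int] = {}
    for i in range(nb):
        zi = z[:, batches.codes == i]
        g, d = gamma_hat[i].copy(), delta_hat[i].copy()
        for it in range(1, max_iter + 1):
            g_new = (n_i[i] * tau_sq[i] * gamma_hat[i] + d * gamma_bar[i]) / (
                n_i[i] * tau_sq[i] + d
            )
            ss = ((zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[i] + 0.5 * ss) / (n_i[i] / 2.0 + lam[i] - 1.0)
            change = max(np.abs(g_new - g).max(), np.abs(d_new - d).max())
            g, d = g_new, d_new
            if change < conv:
                break
        iters[str(batches.categories[i])] = it
        gamma_star[i], delta_star[i] = g, d
    # neutral parameters for pass-through probes
    gamma_star[:, flat] = 0.0
    delta_star[:, flat] = 1.0

    cats = [str(c) for c in batches.categories]
    probe_ids = m.probe_ids
    return BatchCorrectionModel(
        batch_level=batch_level,
        covariates=tuple(covariates),
        alpha=pd.Series(alpha, index=probe_ids),
        sigma=pd.Series(sigma, index=probe_ids),
        stand_mean=pd.DataFrame(stand_mean, index=probe_ids, columns=m.sample_ids),
        batch_of=pd.Series(
            [str(b) for b in df[batch_level]], index=m.sample_ids
        ),
        batch_sizes=pd.Series(n_i, index=cats),
        gamma_hat=pd.DataFrame(gamma_hat, index=cats, columns=probe_ids),
        delta_hat_sq=pd.DataFrame(delta_hat, index=cats, columns=probe_ids),
        gamma_star=pd.DataFrame(gamma_star, index=cats, columns=probe_ids),
        delta_star_sq=pd.DataFrame(delta_star, index=cats, columns=probe_ids),
        hyper=pd.DataFrame(
            {"gamma_bar": gamma_bar, "tau_bar_sq": tau_sq,
             "lambda_": lam, "theta": theta},
            index=cats,
        ),
        n_iter=iters,
        passthrough_probes=passthrough,
    )


def combat_apply(m: ExpressionMatrix, model: BatchCorrectionModel) -> ExpressionMatrix:
    """Adjust every sample of ``m`` with its batch's shrunken parameters."""
    unknown = [s for s in m.sample_ids if s not in model.batch_of.index]
    if unknown:
        raise DataError(f"samples not seen at fit time: {unknown}")
    if list(m.probe_ids) != list(model.alpha.index):
        raise DataError("probe set/order differs from the fitted model")
    y = m.values.to_numpy()
    stand = model.stand_mean[m.sample_ids].to_numpy()
    sigma = model.sigma.to_numpy()
    z = (y - stand) / sigma[:, None]
    out = np.empty_like(y)
    for j, sid in enumerate(m.sample_ids):
        b = model.batch_of[sid]
        g = model.gamma_star.loc[b].to_numpy()
        d = np.sqrt(model.delta_star_sq.loc[b].to_numpy())
        out[:, j] = sigma / d * (z[:, j] - g) + stand[:, j]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids),
        m.detection.copy() if m.detection is not None else None,
    )


def combat(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    batch_level: str,
    covariates: Sequence[str] = (),
) -> ExpressionMatrix:
    """Fit and apply in one step."""
    return combat_apply(m, combat_fit(m, sheet, batch_level, covariates))


def combat_sequential(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    batch_levels: Sequence[str],
    covariates: Sequence[str] = (),
) -> ExpressionMatrix:
    """Correct at several nested levels, outermost first."""
    out = m
    for lvl in batch_levels:
        out = combat(out, sheet, lvl, covariates)
    return out


def mean_center(
    m: ExpressionMatrix, sheet: SampleSheet, batch_level: str
) -> ExpressionMatrix:
    """Per probe: subtract each batch's mean, add back the grand mean."""
    df = sheet.aligned_to(m.sample_ids)
    y = m.values.to_numpy()
    batches = pd.Categorical(df[batch_level])
    grand = y.mean(axis=1, keepdims=True)
    out = y.copy()
    for i in range(len(batches.categories)):
        mask = batches.codes == i
        out[:, mask] = y[:, mask] - y[:, mask].mean(axis=1, keepdims=True) + grand
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids),
        m.detection.copy() if m.detection is not None else None,
    )
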
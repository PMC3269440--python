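"""Detection filtering, quantile normalisation, and pairwise correlations.

The detection filter removes a probe when its confidence is <= the threshold
in strictly more than the allowed fraction of samples (both inequalities
strict, applied before any normalisation).  Quantile normalisation forces
every sample onto the reference distribution built from rank-wise means; tied
values receive the mean of the reference values at their tied ranks, which
keeps the operation idempotent and deterministic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DataError, ExpressionMatrix


def detection_filter(
    m: ExpressionMatrix,
    conf_threshold: float = 0.95,
    max_fail_fraction: float = 0.20,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop probes failing detection in more than ``max_fail_fraction`` of samples.

    A sample "fails" a probe when its detection confidence is <= ``conf_threshold``.
    The probe is removed iff (failures / n_samples) > ``max_fail_fraction``,
    strictly; surviving probes keep their original order.
    """
    if m.detection is None:
        raise DataError(
            "matrix has no detection grid; either supply one or skip "
            "detection filtering explicitly"
        )
    fails = (m.detection.to_numpy() <= conf_threshold).sum(axis=1)
    frac = fails / m.shape[1]
    keep_mask = frac <= max_fail_fraction
    removed = [p for p, k in zip(m.probe_ids, keep_mask) if not k]
    kept = [p for p, k in zip(m.probe_ids, keep_mask) if k]
    filtered = ExpressionMatrix(
        m.values.loc[kept], m.detection.loc[kept] if m.detection is not None else None
    )
    return filtered, removed


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Quantile-normalise columns of a 2-D array, averaging ties."""
    n, s = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(x)
    for j in range(s):
        col = x[:, j]
        ranks = np.empty(n, dtype=np.intp)
        ranks[order[:, j]] = np.arange(n)
        mapped = reference[ranks]
        # average the reference over tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=mapped)
            counts = np.bincount(inv)
            mapped = (sums / counts)[inv]
        out[:, j] = mapped
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Array-wise quantile normalisation onto the rank-wise mean reference."""
    x = m.values.to_numpy()
    if np.isnan(x).any():
        raise DataError("missing values present; imputation is out of scope")
    if m.shape[1] == 1:
        return m.copy()
    out = _quantile_normalize_array(x)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids),
        m.detection.copy() if m.detection is not None else None,
    )


def pairwise_correlation(
    m: ExpressionMatrix, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlations between sample columns, as percentages.

    Entry (i, j) is 100 * Pearson r over all retained probes; the diagonal
    is exactly 100.
    """
    cols = list(subset) if subset is not None else m.sample_ids
    if len(cols) < 2:
        raise DataError("need at least two samples to correlate")
    if m.shape[0] < 2:
        raise DataError("need at least two probes to correlate")
    x = m.values[cols].to_numpy()
    sd = x.std(axis=0)
    zero = [c for c, s in zip(cols, sd) if s == 0]
    if zero:
        raise DataError(f"zero-variance sample column(s): {zero}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(100.0 * r, index=cols, columns=cols)
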
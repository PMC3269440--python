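"""Probe-composition analyses: GC content vs batch variability, and
probe-position vs variability checks.

Low-GC probes hybridise less stably, so their reported expressions are more
vulnerable to systematic batch error; the enrichment test cross-tabulates
(GC below a cutoff) x (level SD above a cutoff) and applies Pearson's
chi-squared without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, ProbeSheet

GC_CUTOFF = 0.55
SD_QUANTILE = 0.90


@dataclass
class EnrichmentResult:
    table: pd.DataFrame        # 2x2 observed counts
    statistic: float
    p_value: float
    sd_cut: float
    gc_cut: float
    unreliable: bool           # an expected cell count fell below 5


def chi2_stat(table: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (obs - expected) ** 2 / expected
    stat = float(np.nansum(cells))
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, dof)) if stat > 0 else 1.0
    return stat, p, expected


def gc_sd_enrichment(
    sd: pd.Series | Sequence[float],
    gc: pd.Series | Sequence[float],
    gc_cut: float = GC_CUTOFF,
    sd_cut: float | None = None,
) -> EnrichmentResult:
    """Cross-tabulate (gc < gc_cut) x (sd > sd_cut) and test for enrichment.

    ``sd_cut`` defaults to the 90th percentile of the SD vector, making the
    result invariant to monotone transforms of the SDs.
    """
    sd = pd.Series(sd).astype(float)
    gc = pd.Series(gc).astype(float)
    if len(sd) != len(gc):
        raise DataError("sd and gc vectors must align on the same probes")
    mask = sd.notna() & gc.notna()
    sd, gc = sd[mask].to_numpy(), gc[mask].to_numpy()
    if sd_cut is None:
        sd_cut = float(np.quantile(sd, SD_QUANTILE))
    low_gc = gc < gc_cut
    high_sd = sd > sd_cut
    if low_gc.all() or (~low_gc).all() or high_sd.all() or (~high_sd).all():
        raise DataError("a cutoff is not interior to its vector")
    table = pd.DataFrame(
        [
            [int((low_gc & high_sd).sum()), int((low_gc & ~high_sd).sum())],
            [int((~low_gc & high_sd).sum()), int((~low_gc & ~high_sd).sum())],
        ],
        index=["gc<cut", "gc>=cut"],
        columns=["sd>cut", "sd<=cut"],
    )
    stat, p, expected = chi2_stat(table.to_numpy())
    return EnrichmentResult(
        table=table,
        statistic=stat,
        p_value=p,
        sd_cut=float(sd_cut),
        gc_cut=float(gc_cut),
        unreliable=bool((expected < 5).any()),
    )


@dataclass
class DistributionShift:
    grid: np.ndarray
    density_universe: np.ndarray
    density_selected: np.ndarray
    statistic: float
    p_value: float
    underpowered: bool


def gc_distribution_shift(
    selected: Iterable[str],
    universe: ProbeSheet,
    bandwidth: float = 0.02,
    bin_width: float = 0.05,
) -> DistributionShift:
    """Gaussian-smoothed GC densities for all probes vs a selected subset,
    with a chi-squared goodness-of-fit test on counts binned over [0, 1].

    The selected probes' binned counts are tested against expectations
    proportional to the universe's bin occupancy.
    """
    gc_all = universe.gc()
    sel_ids = [s for s in selected]
    missing = [s for s in sel_ids if s not in gc_all.index]
    if missing:
        raise DataError(f"selected probes not in universe: {missing[:5]} ...")
    gc_sel = gc_all.loc[sel_ids]

    grid = np.linspace(0.0, 1.0, 201)

    def smooth(vals: np.ndarray) -> np.ndarray:
        # Gaussian kernel density with a fixed absolute bandwidth
        diffs = (grid[:, None] - vals[None, :]) / bandwidth
        dens = np.exp(-0.5 * diffs**2).sum(axis=1)
        return dens / (len(vals) * bandwidth * np.sqrt(2 * np.pi))

    d_all = smooth(gc_all.to_numpy())
    d_sel = smooth(gc_sel.to_numpy())

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts_all, _ = np.histogram(gc_all, bins=edges)
    counts_sel, _ = np.histogram(gc_sel, bins=edges)
    keep = counts_all > 0
    expected = counts_all[keep] / counts_all[keep].sum() * counts_sel.sum()
    observed = counts_sel[keep]
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, keep.sum() - 1)) if stat > 0 else 1.0
    return DistributionShift(
        grid=grid,
        density_universe=d_all,
        density_selected=d_sel,
        statistic=stat,
        p_value=p,
        underpowered=len(sel_ids) < 20,
    )


@dataclass
class TrendResult:
    rho: float
    p_value: float
    n_permutations: int


def position_sd_association(
    sd: pd.Series,
    probes: ProbeSheet,
    n_permutations: int = 1000,
    seed: int = 0,
) -> TrendResult:
    """Spearman correlation between probe position fraction and SD, with a
    two-sided permutation p value (positions already strand-normalised)."""
    if "probe_position_fraction" not in probes.frame.columns:
        raise DataError("probe sheet lacks probe_position_fraction")
    pos = probes.frame.set_index("probe_id")["probe_position_fraction"].astype(float)
    sd = pd.Series(sd).astype(float)
    common = sd.index.intersection(pos.index)
    sd, pos = sd.loc[common], pos.loc[common]
    mask = sd.notna() & pos.notna()
    sd, pos = sd[mask].to_numpy(), pos[mask].to_numpy()
    if np.ptp(pos) == 0.0:
        raise DataError("all probe positions identical; no trend to test")
    rho = float(stats.spearmanr(pos, sd).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(sd)
        if abs(stats.spearmanr(pos, perm).statistic) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return TrendResult(rho=rho, p_value=float(p), n_permutations=n_permutations)
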
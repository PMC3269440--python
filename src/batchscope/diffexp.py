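"""Differential expression with fold-change and FDR criteria.

A probe is called differentially expressed when it satisfies both a minimum
fold-change on the natural scale (|FC| >= fc_min, i.e. 2^|log2 difference|)
and a Benjamini-Hochberg adjusted p value at most ``p_max``.  Plain t tests
(Welch for two independent groups, paired otherwise) are used; an optional
variance floor (per-probe SD floored at the cross-probe median) is available
for small-sample stability but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DataError, ExpressionMatrix, SampleSheet


@dataclass
class DEResult:
    table: pd.DataFrame  # per probe: t, p, p_adj, log2fc, significant
    group_a: str
    group_b: str
    design: str

    @property
    def significant(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def _two_groups(df: pd.DataFrame) -> tuple[str, str, pd.Series]:
    bio = df[df["role"] == "biological"]
    groups = bio["group"].dropna().drop_duplicates().tolist()
    if len(groups) != 2:
        raise DataError(f"need exactly two biological groups, found {groups}")
    return groups[0], groups[1], bio.set_index("sample_id")["group"]


def de_test(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    design: str = "two_group",
    fc_min: float = 1.5,
    p_max: float = 0.01,
    pair_col: str = "duplicate_id",
    variance_floor: bool = False,
) -> DEResult:
    """Per-probe t test (Welch or paired) with BH adjustment.

    ``design`` is "two_group" or "paired"; a paired design matches samples of
    the two groups through ``pair_col`` and requires complete pairs.  The
    log2 fold-change is group_b minus group_a (groups in sheet order).
    """
    df = sheet.aligned_to(m.sample_ids)
    ga, gb, group_of = _two_groups(df)
    a_ids = [s for s in m.sample_ids if group_of.get(s) == ga]
    b_ids = [s for s in m.sample_ids if group_of.get(s) == gb]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise DataError("each group needs at least two samples")
    A = m.values[a_ids].to_numpy()
    B = m.values[b_ids].to_numpy()

    if design == "paired":
        bio = df[df["role"] == "biological"]
        if pair_col not in bio.columns:
            raise DataError(f"paired design needs a {pair_col!r} column")
        pairs: dict[str, dict[str, str]] = {}
        for _, row in bio.iterrows():
            key = row[pair_col]
            if pd.isna(key):
                raise DataError(f"sample {row['sample_id']} has no {pair_col}")
            pairs.setdefault(str(key), {})[row["group"]] = row["sample_id"]
        incomplete = [k for k, v in pairs.items() if set(v) != {ga, gb}]
        if incomplete:
            raise DataError(f"incomplete pairs for subjects: {sorted(incomplete)}")
        keys = sorted(pairs)
        A = m.values[[pairs[k][ga] for k in keys]].to_numpy()
        B = m.values[[pairs[k][gb] for k in keys]].to_numpy()
        diffs = B - A
        lfc = diffs.mean(axis=1)
        sd = diffs.std(axis=1, ddof=1)
        if variance_floor:
            sd = np.maximum(sd, np.median(sd))
        n = diffs.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / (sd / np.sqrt(n))
        t = np.where((sd == 0) & (lfc == 0), 0.0, t)
        p = 2 * stats.t.sf(np.abs(t), n - 1)
    elif design == "two_group":
        lfc = B.mean(axis=1) - A.mean(axis=1)
        va = A.var(axis=1, ddof=1)
        vb = B.var(axis=1, ddof=1)
        if variance_floor:
            floor = np.median(np.concatenate([va, vb]))
            va = np.maximum(va, floor)
            vb = np.maximum(vb, floor)
        na, nb = A.shape[1], B.shape[1]
        se2 = va / na + vb / nb
        # probes with no within-group variance at all carry no evidence
        zero = se2 == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero, 0.0, lfc / np.sqrt(se2))
            dof = np.where(
                zero,
                1.0,
                se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
            )
        p = np.where(zero, 1.0, 2 * stats.t.sf(np.abs(t), dof))
    else:
        raise DataError(f"unknown design {design!r}; use 'two_group' or 'paired'")

    _, p_adj, *_ = multipletests(p, method="fdr_bh")
    sig = (2.0 ** np.abs(lfc) >= fc_min) & (p_adj <= p_max)
    table = pd.DataFrame(
        {"t": t, "p": p, "p_adj": p_adj, "log2fc": lfc, "significant": sig},
        index=m.probe_ids,
    )
    return DEResult(table=table, group_a=ga, group_b=gb, design=design)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p values (monotone, capped at 1)."""
    _, p_adj, *_ = multipletests(np.asarray(p, dtype=float), method="fdr_bh")
    return p_adj


def list_concordance(
    lists: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
) -> dict:
    """Pairwise and common intersection sizes across DE probe-id sets."""
    if isinstance(lists, Mapping):
        named = {str(k): set(v) for k, v in lists.items()}
    else:
        named = {f"list{i + 1}": set(v) for i, v in enumerate(lists)}
    if len(named) < 2:
        raise DataError("need at least two lists")
    names = list(named)
    pairwise = {
        (a, b): len(named[a] & named[b])
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    common = set.intersection(*named.values())
    return {
        "pairwise": pairwise,
        "common": len(common),
        "common_ids": sorted(common),
        "sizes": {k: len(v) for k, v in named.items()},
    }
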
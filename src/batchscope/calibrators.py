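"""Batch-shift tables and calibrator-fidelity comparisons.

A *shift* is the per-probe log2 expression difference of the same RNA
hybridised in two different batches: for technical duplicates of a clinical
sample it isolates that sample's batch response, and for replicate control
samples (generic UHRR-like controls, or pools mixed from the study's own
samples) it measures how well the control tracks that response.  Shift signs
are oriented by lexicographic batch-label order so they cancel consistently
in correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, ExpressionMatrix, SampleSheet

DEFAULT_MAGNITUDE_BINS = (0.0, 0.5, 1.0, 1.5)


@dataclass
class ShiftTable:
    """Per-probe expression difference between two batches for one pair."""

    pair_id: str
    kind: str  # sample_duplicate | generic_control | pooled_control
    batch_from: str
    batch_to: str
    delta: pd.Series  # probes, log2(to) - log2(from)

    @property
    def batch_pair(self) -> tuple[str, str]:
        return (self.batch_from, self.batch_to)


def _oriented(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def batch_shifts(
    m: ExpressionMatrix, sheet: SampleSheet, batch_level: str
) -> list[ShiftTable]:
    """One ShiftTable per eligible duplicate pair and control replicate pair.

    Duplicate ids with more than two samples yield every cross-batch pairing;
    pairs falling in the same batch are skipped with a warning.  Control
    replicate sets are grouped by their replicate label (``duplicate_id``)
    when present, else by role.
    """
    df = sheet.aligned_to(m.sample_ids)
    batch = df.set_index("sample_id")[batch_level]
    role = df.set_index("sample_id")["role"]
    tables: list[ShiftTable] = []

    def add_pairs(members: Sequence[str], kind: str, label: str) -> None:
        for s1, s2 in combinations(members, 2):
            b1, b2 = str(batch[s1]), str(batch[s2])
            if b1 == b2:
                if kind == "sample_duplicate":
                    warnings.warn(
                        f"duplicate pair {label} ({s1}, {s2}) falls in one "
                        f"{batch_level}; skipped",
                        stacklevel=2,
                    )
                continue
            (bf, bt) = _oriented(b1, b2)
            first, second = (s1, s2) if (b1, b2) == (bf, bt) else (s2, s1)
            delta = m.values[second] - m.values[first]
            tables.append(
                ShiftTable(
                    pair_id=f"{label}:{first}-{second}",
                    kind=kind,
                    batch_from=bf,
                    batch_to=bt,
                    delta=delta,
                )
            )

    bio = df[df["role"] == "biological"]
    for dup_id, sub in bio[bio["duplicate_id"].notna()].groupby(
        "duplicate_id", sort=False
    ):
        add_pairs(sub["sample_id"].tolist(), "sample_duplicate", str(dup_id))

    for ctrl_role, kind in (
        ("generic_control", "generic_control"),
        ("pooled_control", "pooled_control"),
    ):
        sub = df[df["role"] == ctrl_role]
        if not len(sub):
            continue
        labels = sub["duplicate_id"].fillna(ctrl_role)
        for lab, reps in sub.groupby(labels, sort=False):
            add_pairs(reps["sample_id"].tolist(), kind, str(lab))
    return tables


def calibrator_fidelity(
    control: ShiftTable,
    sample: ShiftTable,
    magnitude_bins: Sequence[float] = DEFAULT_MAGNITUDE_BINS,
) -> dict[float, float | None]:
    """Pearson r (%) between control and sample shifts, overall and restricted
    to probes whose |sample shift| meets each cumulative threshold.

    Bins with fewer than three probes (or degenerate variance) map to None.
    """
    if control.batch_pair != sample.batch_pair:
        raise DataError(
            f"batch pairs differ: control {control.batch_pair} vs "
            f"sample {sample.batch_pair}"
        )
    if list(control.delta.index) != list(sample.delta.index):
        raise DataError("control and sample shift tables cover different probes")
    out: dict[float, float | None] = {}
    c = control.delta.to_numpy()
    s = sample.delta.to_numpy()
    for thr in magnitude_bins:
        mask = np.abs(s) >= thr
        if mask.sum() < 3 or np.std(c[mask]) == 0 or np.std(s[mask]) == 0:
            out[float(thr)] = None
            continue
        r = np.corrcoef(c[mask], s[mask])[0, 1]
        out[float(thr)] = float(100.0 * r)
    return out


def compare_calibrators(
    fidelities_a: Sequence[float], fidelities_b: Sequence[float]
) -> tuple[float, float]:
    """One-sample two-tailed t-test on the paired differences (a - b).

    Returns (mean difference in correlation percentage points, p value).
    Zero-variance non-zero differences are degenerate: p is NaN.
    """
    a = np.asarray(list(fidelities_a), dtype=float)
    b = np.asarray(list(fidelities_b), dtype=float)
    if a.shape != b.shape:
        raise DataError("fidelity lists must be paired (equal length)")
    if len(a) < 2:
        raise DataError("need at least two pairs to compare calibrators")
    d = a - b
    mean = float(d.mean())
    if d.std(ddof=1) == 0.0:
        return (mean, 1.0 if mean == 0.0 else float("nan"))
    t, p = stats.ttest_1samp(d, 0.0)
    return (mean, float(p))


def count_batch_regulated(
    shifts: Sequence[ShiftTable],
    fold_threshold: float = 2.0,
    min_pairs: int = 1,
) -> set[str]:
    """Probes more than ``fold_threshold``-fold shifted (strictly) in at least
    ``min_pairs`` of the duplicate-sample pairs."""
    if fold_threshold <= 1.0:
        raise DataError("fold_threshold must exceed 1")
    dup = [t for t in shifts if t.kind == "sample_duplicate"]
    if not dup:
        raise DataError("no sample-duplicate shift tables supplied")
    cut = np.log2(fold_threshold)
    counts = sum((t.delta.abs() > cut).astype(int) for t in dup)
    return set(counts.index[counts >= min_pairs])
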
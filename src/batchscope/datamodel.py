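"""Core containers for expression data, sample annotation, and probe annotation.

All expression values are log2-scale intensities held in a pandas DataFrame
(probes as rows, samples as columns).  A sample sheet assigns every array a
role (biological sample, generic control such as UHRR, or pooled control), an
optional biological group, an optional duplicate identifier linking technical
duplicates of one source RNA, and strictly nested batch coordinates
(experiment > run > chip > array position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Ordered batch coordinates, outermost first.  The innermost coordinate
#: (array position) carries the residual; one sample per array.
BATCH_LEVELS: tuple[str, ...] = ("experiment", "run", "chip", "array_position")

ROLES = ("biological", "generic_control", "pooled_control")


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()].tolist()))
        raise DataError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities with optional detection confidences.

    ``values`` is indexed by probe id with sample ids as columns.
    ``detection``, when present, has identical index/columns and entries in
    [0, 1] (larger means more confidently detected above background).
    """

    values: pd.DataFrame
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        if self.detection is not None:
            det = pd.DataFrame(self.detection).astype(float)
            det.index = det.index.astype(str)
            det.columns = det.columns.astype(str)
            extra_p = det.index.difference(self.values.index).tolist()
            missing_p = self.values.index.difference(det.index).tolist()
            extra_s = det.columns.difference(self.values.columns).tolist()
            missing_s = self.values.columns.difference(det.columns).tolist()
            if extra_p or missing_p or extra_s or missing_s:
                raise DataError(
                    "detection grid does not match expression grid: "
                    f"extra probes {extra_p}, missing probes {missing_p}, "
                    f"extra samples {extra_s}, missing samples {missing_s}"
                )
            det = det.loc[self.values.index, self.values.columns]
            arr = det.to_numpy()
            if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
                raise DataError("detection confidences must lie in [0, 1]")
            self.detection = det

    # -- convenience ---------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = [p for p in self.probe_ids if p in set(probe_ids)]
        det = self.detection.loc[idx] if self.detection is not None else None
        return ExpressionMatrix(self.values.loc[idx], det)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        cols = list(sample_ids)
        det = self.detection[cols] if self.detection is not None else None
        return ExpressionMatrix(self.values[cols], det)

    def copy(self) -> "ExpressionMatrix":
        det = self.detection.copy() if self.detection is not None else None
        return ExpressionMatrix(self.values.copy(), det)

    def equals(self, other: "ExpressionMatrix", tol: float = 0.0) -> bool:
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        return bool(np.all(np.abs(a - b) <= tol))


@dataclass
class SampleSheet:
    """Per-sample annotation: role, biological group, duplicates, batches.

    The underlying frame has one row per sample with columns ``sample_id``,
    ``role``, ``group``, ``duplicate_id`` and the :data:`BATCH_LEVELS`.
    Missing group/duplicate are held as NaN/None.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        required = ["sample_id", "role"] + list(BATCH_LEVELS)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataError(f"sample sheet missing columns: {missing}")
        for col in ("group", "duplicate_id"):
            if col not in df.columns:
                df[col] = pd.NA
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids")
        bad_roles = sorted(set(df["role"]) - set(ROLES))
        if bad_roles:
            raise DataError(f"unknown roles: {bad_roles} (allowed: {ROLES})")
        ctrl_with_group = df[
            df["role"].isin(("generic_control", "pooled_control"))
            & df["group"].notna()
        ]
        if len(ctrl_with_group):
            raise DataError(
                "control samples must not carry a biological group: "
                f"{ctrl_with_group['sample_id'].tolist()}"
            )
        for lvl in BATCH_LEVELS:
            df[lvl] = df[lvl].astype(str)
        self._validate_nesting(df)
        self.frame = df.reset_index(drop=True)

    @staticmethod
    def _validate_nesting(df: pd.DataFrame) -> None:
        # every inner-level label must occur under exactly one outer unit
        for outer, inner in zip(BATCH_LEVELS[:-1], BATCH_LEVELS[1:-1]):
            parents = df.groupby(inner, sort=False)[outer].nunique()
            bad = parents[parents > 1].index.tolist()
            if bad:
                raise DataError(
                    f"{inner} label(s) {bad} occur under more than one {outer}; "
                    "batch coordinates must be strictly nested"
                )

    # -- accessors -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Rows reordered to ``sample_ids``; error on absent/extra samples."""
        df = self.frame.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise DataError(f"samples absent from sample sheet: {missing}")
        return df.loc[list(sample_ids)].reset_index()

    def batch_of(self, level: str) -> pd.Series:
        if level not in BATCH_LEVELS:
            raise DataError(f"unknown batch level {level!r}; expected one of {BATCH_LEVELS}")
        return self.frame.set_index("sample_id")[level]

    def samples_with_role(self, role: str) -> list[str]:
        return self.frame.loc[self.frame["role"] == role, "sample_id"].tolist()

    def duplicate_groups(self) -> dict[str, list[str]]:
        df = self.frame[self.frame["duplicate_id"].notna()]
        return {
            str(k): v["sample_id"].tolist()
            for k, v in df.groupby("duplicate_id", sort=False)
        }

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        sheet_ids = set(self.sample_ids)
        mat_ids = set(matrix.sample_ids)
        if sheet_ids != mat_ids:
            raise DataError(
                "sample sheet and matrix disagree: "
                f"only in sheet {sorted(sheet_ids - mat_ids)}, "
                f"only in matrix {sorted(mat_ids - sheet_ids)}"
            )


def gc_fraction(sequence: str) -> float:
    """G+C proportion of a DNA sequence; 'N' bases are excluded entirely."""
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise DataError(f"sequence contains non-DNA characters: {sorted(bad)}")
    counted = [b for b in seq if b != "N"]
    if not counted:
        raise DataError("sequence has no countable (non-N) bases")
    gc = sum(b in "GC" for b in counted)
    return gc / len(counted)


@dataclass
class ProbeSheet:
    """Probe annotation: sequence, GC fraction, optional gene mapping.

    ``probe_position_fraction`` is the probe start as a fraction of the target
    gene length measured on the sense strand; probes mapping antisense are
    expected to have been flipped (fraction := 1 - raw) upstream.
    """

    frame: pd.DataFrame

    OPTIONAL = ("gene_id", "strand", "probe_position_fraction", "n_transcripts", "n_exons")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        if "probe_id" not in df.columns:
            raise DataError("probe sheet requires a probe_id column")
        df["probe_id"] = df["probe_id"].astype(str)
        _check_unique(df["probe_id"], "probe ids")
        if "sequence" in df.columns and df["sequence"].notna().any():
            computed = df["sequence"].map(gc_fraction)
            if "gc_fraction" in df.columns and df["gc_fraction"].notna().any():
                diff = (df["gc_fraction"].astype(float) - computed).abs()
                if (diff > 1e-9).any():
                    bad = df.loc[diff > 1e-9, "probe_id"].tolist()
                    raise DataError(f"gc_fraction inconsistent with sequence for {bad}")
            df["gc_fraction"] = computed
        if "gc_fraction" in df.columns:
            g = df["gc_fraction"].astype(float)
            if ((g < 0) | (g > 1)).any():
                raise DataError("gc_fraction must lie in [0, 1]")
        if "probe_position_fraction" in df.columns:
            p = pd.to_numeric(df["probe_position_fraction"], errors="coerce")
            ok = p.isna() | ((p >= 0) & (p <= 1))
            if not ok.all():
                raise DataError("probe_position_fraction must lie in [0, 1]")
        if "strand" in df.columns:
            bad = set(df["strand"].dropna()) - {"+", "-"}
            if bad:
                raise DataError(f"strand entries must be '+' or '-', got {sorted(bad)}")
        self.frame = df.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return self.frame["probe_id"].tolist()

    def gc(self) -> pd.Series:
        return self.frame.set_index("probe_id")["gc_fraction"].astype(float)
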
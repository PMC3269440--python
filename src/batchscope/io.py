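"""Readers and writers for the delimited-text interchange formats.

Expression matrices, sample sheets, and probe sheets travel as plain TSV
(first column ``probe_id`` / ``sample_id``, strings unquoted); probe
sequences travel as FASTA.  Floats are written with 17 significant digits so
a write/read round trip is the identity well beyond 12 significant digits.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    DataError,
    ExpressionMatrix,
    ProbeSheet,
    SampleSheet,
    gc_fraction,
)

_FLOAT_FMT = "%.17g"


def _read_grid(path: str | os.PathLike, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        body = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise DataError(f"non-numeric value in {what} body of {path}: {exc}") from exc
    return body


def read_expression(
    path: str | os.PathLike, detection_path: str | os.PathLike | None = None
) -> ExpressionMatrix:
    """Read a probes x samples TSV (and optional detection grid)."""
    values = _read_grid(path, "expression")
    detection = _read_grid(detection_path, "detection") if detection_path else None
    return ExpressionMatrix(values, detection)


def write_expression(
    m: ExpressionMatrix,
    path: str | os.PathLike,
    detection_path: str | os.PathLike | None = None,
) -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT)
    if detection_path is not None:
        if m.detection is None:
            raise DataError("matrix has no detection grid to write")
        m.detection.to_csv(
            detection_path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT
        )


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("group", "duplicate_id"):
        if col in df.columns:
            df[col] = df[col].mask(df[col] == "", pd.NA)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_probe_sheet(path: str | os.PathLike) -> ProbeSheet:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return ProbeSheet(df)


def write_probe_sheet(sheet: ProbeSheet, path: str | os.PathLike) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_probe_fasta(path: str | os.PathLike) -> ProbeSheet:
    """Read probe sequences from FASTA; GC fraction is computed per record.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are rejected,
    as are empty sequences and duplicate record ids.
    """
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = str(rec.id)
        if pid in seen:
            raise DataError(f"duplicate FASTA id: {pid}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if not seq:
            raise DataError(f"empty sequence for FASTA record {pid}")
        ids.append(pid)
        seqs.append(seq)
    frame = pd.DataFrame(
        {
            "probe_id": ids,
            "sequence": seqs,
            "gc_fraction": [gc_fraction(s) for s in seqs],
        }
    )
    return ProbeSheet(frame)


def write_probe_fasta(sheet: ProbeSheet, path: str | os.PathLike) -> None:
    if "sequence" not in sheet.frame.columns:
        raise DataError("probe sheet has no sequences to write")
    with open(path, "w") as fh:
        for pid, seq in zip(sheet.frame["probe_id"], sheet.frame["sequence"]):
            fh.write(f">{pid}\n{seq}\n")
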
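"""Core tabular containers for breath-VOC analysis.

A breath cohort is represented by three aligned tables:

* :class:`PeakTable` — samples x compounds peak areas from GC-MS peak
  integration (arbitrary area units, NaN = missing/invalid measurement);
* :class:`SnrTable` — same-shape chromatographic signal-to-noise ratios;
* a sample sheet (plain :class:`pandas.DataFrame`) carrying per-sample
  diagnosis labels, subtype, AJCC stage, pre/post-operative timepoint,
  pairing, and optional serum tumour-marker values.

All on-disk formats are plain text: TSV for the matrices (samples as rows,
first column ``sample_id``, header row of compound ids) and CSV for the
sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "SnrTable",
    "SAMPLE_SHEET_COLUMNS",
    "SERUM_MARKERS",
    "validate_sample_sheet",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
]

#: Required sample-sheet columns, in canonical order.
SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "class",
    "subtype",
    "stage",
    "timepoint",
    "pair_id",
    "ca125",
    "progrp",
    "cea",
    "cyfra211",
]

#: Serum tumour markers and the upper limit of their clinical normal range.
#: CA125 in KU/L, ProGRP in ng/L, CEA in ug/L, CYFRA21-1 in ng/L.
SERUM_MARKERS = {"ca125": 35.0, "progrp": 46.0, "cea": 5.0, "cyfra211": 3.0}

CLASSES = ("malignant", "benign")
SUBTYPES = ("LC", "thymoma", "EC", "benign_nodule", "benign_other")
STAGES = ("0", "I", "II", "III", "IV", "unknown")
TIMEPOINTS = ("preop", "postop")


def _check_axes(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids")
    if df.columns.has_duplicates:
        raise ValueError("duplicate compound ids")


@dataclass
class PeakTable:
    """Samples x compounds matrix of non-negative peak areas.

    ``areas`` is indexed by sample id with compound ids as columns; NaN
    entries mark missing (invalid) measurements.  ``retention_times`` is an
    optional per-compound retention time in minutes.
    """

    areas: pd.DataFrame
    retention_times: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_axes(self.areas)
        vals = self.areas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative peak areas")
        if self.retention_times is not None:
            self.retention_times = self.retention_times.reindex(self.areas.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.areas.columns)

    def restrict(self, samples=None, compounds=None) -> "PeakTable":
        """Return a copy limited to the given sample/compound ids (order kept)."""
        df = self.areas
        if samples is not None:
            df = df.loc[list(samples)]
        if compounds is not None:
            df = df[list(compounds)]
        rt = None
        if self.retention_times is not None:
            rt = self.retention_times.reindex(df.columns)
        return PeakTable(df.copy(), rt)


@dataclass
class SnrTable:
    """Signal-to-noise ratios on the same axes as a paired :class:`PeakTable`."""

    snr: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.snr)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.snr.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.snr.columns)

    def check_aligned(self, peaks: PeakTable) -> None:
        if list(self.snr.index) != peaks.sample_ids or list(self.snr.columns) != peaks.compound_ids:
            raise ValueError("SNR table axes do not match the peak table")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a sample sheet.

    Raises ``ValueError`` on missing columns, duplicate sample ids, or
    labels outside the allowed vocabularies.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SAMPLE_SHEET_COLUMNS].copy()
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    for col, allowed in (("class", CLASSES), ("subtype", SUBTYPES),
                         ("stage", STAGES), ("timepoint", TIMEPOINTS)):
        bad = set(sheet[col].astype(str)) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} labels: {sorted(bad)}")
        sheet[col] = sheet[col].astype(str)
    for m in SERUM_MARKERS:
        sheet[m] = pd.to_numeric(sheet[m], errors="coerce")
    return sheet


# ---------------------------------------------------------------------------
# plain-text I/O

def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False, float_format="%.10g",
                                        lineterminator="\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "pair_id": str})
    sheet["pair_id"] = sheet["pair_id"].fillna("")
    return validate_sample_sheet(sheet)
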
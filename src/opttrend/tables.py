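"""Domain types and I/O for case-control genotype count data.

A biallelic marker with alleles ``a`` and ``A`` yields three genotypes,
indexed by the number of copies of the ``A`` allele: ``aa`` (0), ``Aa`` (1)
and ``AA`` (2).  A case-control study is summarised by a 2x3 contingency
table of genotype counts: cases ``(r_0, r_1, r_2)`` over controls
``(s_0, s_1, s_2)``, with column totals ``n_i = r_i + s_i`` and grand total
``n = r + s``.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCounts",
    "SubjectRecord",
    "TableParseError",
    "read_table",
    "write_table",
    "aggregate_subjects",
    "observed_pooled_freqs",
]

GENOTYPE_LABELS = ("aa", "Aa", "AA")

# accepted wide-format header tokens -> genotype index
_GENOTYPE_TOKENS = {"aa": 0, "Aa": 1, "AA": 2, "0": 0, "1": 1, "2": 2}
_CASE_LABELS = {"case", "cases"}
_CONTROL_LABELS = {"control", "controls"}


class TableParseError(ValueError):
    """Raised when genotype count input cannot be parsed or validated."""


def _check_count(value, where: str) -> int:
    """Validate a single cell as a non-negative integer count."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise TableParseError(f"non-numeric count {value!r} in {where}") from None
    if not np.isfinite(f):
        raise TableParseError(f"non-finite count {value!r} in {where}")
    if f != int(f):
        raise TableParseError(
            f"non-integer count {value!r} in {where}; proportions are not accepted"
        )
    if f < 0:
        raise TableParseError(f"negative count {value!r} in {where}")
    return int(f)


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed 2x3 genotype table for a case-control sample.

    Margins (``r``, ``s``, ``n_i``, ``n``) are always recomputed from the
    six cells, never stored.
    """

    cases: tuple[int, int, int]
    controls: tuple[int, int, int]

    def __post_init__(self):
        for name, row in (("cases", self.cases), ("controls", self.controls)):
            if len(row) != 3:
                raise TableParseError(f"{name} must have 3 genotype counts")
            checked = tuple(
                _check_count(v, f"{name}[{GENOTYPE_LABELS[i]}]")
                for i, v in enumerate(row)
            )
            object.__setattr__(self, name, checked)

    # -- margins ---------------------------------------------------------
    @property
    def r(self) -> int:
        return sum(self.cases)

    @property
    def s(self) -> int:
        return sum(self.controls)

    @property
    def n_i(self) -> tuple[int, int, int]:
        return tuple(c + t for c, t in zip(self.cases, self.controls))

    @property
    def n(self) -> int:
        return self.r + self.s

    def case_array(self) -> np.ndarray:
        return np.asarray(self.cases, dtype=float)

    def control_array(self) -> np.ndarray:
        return np.asarray(self.controls, dtype=float)

    def to_subjects(self) -> list["SubjectRecord"]:
        """Expand the table into one record per subject."""
        out: list[SubjectRecord] = []
        for g, k in enumerate(self.cases):
            out.extend(SubjectRecord("case", g) for _ in range(k))
        for g, k in enumerate(self.controls):
            out.extend(SubjectRecord("control", g) for _ in range(k))
        return out

    def to_dict(self) -> dict:
        return {
            "cases": list(self.cases),
            "controls": list(self.controls),
            "margins": {"r": self.r, "s": self.s, "n_i": list(self.n_i), "n": self.n},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: disease status and genotype code (count of A alleles)."""

    status: str
    genotype: int

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise TableParseError(f"unknown status {self.status!r}")
        if self.genotype not in (0, 1, 2):
            raise TableParseError(f"genotype code {self.genotype!r} not in {{0, 1, 2}}")


def aggregate_subjects(records: Iterable[SubjectRecord | tuple]) -> GenotypeCounts:
    """Tally subject-level records into a :class:`GenotypeCounts`.

    Order-invariant.  Tuples ``(status, genotype)`` are accepted as a
    convenience.  An empty record list is an error.
    """
    cases = [0, 0, 0]
    controls = [0, 0, 0]
    k = -1
    for k, rec in enumerate(records):
        if not isinstance(rec, SubjectRecord):
            try:
                rec = SubjectRecord(str(rec[0]).strip().lower(), int(rec[1]))
            except (TableParseError, ValueError, IndexError, TypeError) as e:
                raise TableParseError(f"invalid subject record at index {k}: {e}") from None
        (cases if rec.status == "case" else controls)[rec.genotype] += 1
    if k < 0:
        raise TableParseError("no subjects")
    return GenotypeCounts(tuple(cases), tuple(controls))


# -- reading ------------------------------------------------------------


def _as_buffer(source) -> io.StringIO | str:
    """Interpret `source` as a path if it points to a file, else literal text."""
    if isinstance(source, Path):
        return str(source)
    if isinstance(source, str):
        if "\n" not in source and os.path.exists(source):
            return source
        return io.StringIO(source)
    return source  # already a file-like object


def read_table(source, layout: str = "wide") -> GenotypeCounts:
    """Read a genotype count table from CSV/TSV text or a file path.

    ``wide`` layout: a header naming the three genotype columns (``aa``,
    ``Aa``, ``AA`` or ``0``, ``1``, ``2``) plus a row-label column, and two
    data rows labelled case(s)/control(s).  ``long`` layout: one subject per
    row with columns ``status`` and ``genotype``.  The delimiter (comma or
    tab) is sniffed.
    """
    if layout not in ("wide", "long"):
        raise TableParseError(f"unknown layout {layout!r}")
    buf = _as_buffer(source)
    try:
        df = pd.read_csv(buf, sep=None, engine="python", dtype=str,
                         skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise TableParseError("no subjects" if layout == "long" else "empty table") from None
    df.columns = [str(c).strip() for c in df.columns]
    if layout == "wide":
        return _parse_wide(df)
    return _parse_long(df)


def _parse_wide(df: pd.DataFrame) -> GenotypeCounts:
    geno_cols: dict[int, str] = {}
    label_col = None
    for col in df.columns:
        tok = col.strip()
        if tok in _GENOTYPE_TOKENS:
            idx = _GENOTYPE_TOKENS[tok]
            if idx in geno_cols:
                raise TableParseError(f"duplicate genotype column {col!r}")
            geno_cols[idx] = col
        elif label_col is None:
            label_col = col
    if sorted(geno_cols) != [0, 1, 2]:
        raise TableParseError(
            "wide table must name three genotype columns among "
            "{aa, Aa, AA} or {0, 1, 2}; got " + repr(list(df.columns))
        )
    rows: dict[str, list[int]] = {}
    for ridx, row in df.iterrows():
        if label_col is not None:
            label = str(row[label_col]).strip().lower()
        else:
            label = ("case", "control")[ridx] if ridx < 2 else "?"
        if label in _CASE_LABELS:
            key = "case"
        elif label in _CONTROL_LABELS:
            key = "control"
        else:
            raise TableParseError(f"unknown row label {label!r} (expected case/control)")
        if key in rows:
            raise TableParseError(f"duplicate {key} row")
        rows[key] = [
            _check_count(row[geno_cols[i]], f"row {key!r}, column {geno_cols[i]!r}")
            for i in range(3)
        ]
    for key in ("case", "control"):
        if key not in rows:
            raise TableParseError(f"missing {key} row")
    return GenotypeCounts(tuple(rows["case"]), tuple(rows["control"]))


def _parse_long(df: pd.DataFrame) -> GenotypeCounts:
    cols = {c.lower(): c for c in df.columns}
    if "status" not in cols or "genotype" not in cols:
        raise TableParseError("long table needs 'status' and 'genotype' columns")
    if len(df) == 0:
        raise TableParseError("no subjects")
    records = []
    for k, row in enumerate(df.itertuples(index=False)):
        status = str(getattr(row, cols["status"], row[0])).strip().lower()
        raw_g = df.iloc[k][cols["genotype"]]
        g = _check_count(raw_g, f"row {k}, column 'genotype'")
        if g not in (0, 1, 2):
            raise TableParseError(f"unknown genotype code {raw_g!r} at row {k}")
        if status not in _CASE_LABELS and status not in _CONTROL_LABELS:
            raise TableParseError(f"unknown status {status!r} at row {k}")
        records.append(SubjectRecord("case" if status in _CASE_LABELS else "control", g))
    return aggregate_subjects(records)


def write_table(counts: GenotypeCounts, target=None, layout: str = "wide",
                sep: str = ",") -> str:
    """Serialise a table to CSV/TSV; returns the text, optionally writing it."""
    if layout == "wide":
        lines = [sep.join(["group", *GENOTYPE_LABELS]),
                 sep.join(["case"] + [str(v) for v in counts.cases]),
                 sep.join(["control"] + [str(v) for v in counts.controls])]
    elif layout == "long":
        lines = [sep.join(["status", "genotype"])]
        lines += [sep.join([rec.status, str(rec.genotype)])
                  for rec in counts.to_subjects()]
    else:
        raise TableParseError(f"unknown layout {layout!r}")
    text = "\n".join(lines) + "\n"
    if target is not None:
        Path(target).write_text(text, encoding="utf-8")
    return text


def observed_pooled_freqs(counts: GenotypeCounts) -> np.ndarray:
    """Genotype frequencies in the pooled case-control sample, ``n_i / n``."""
    n = counts.n
    if n == 0:
        raise TableParseError("empty table: n = 0")
    return np.asarray(counts.n_i, dtype=float) / n
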
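"""Desk-computable NMR analyses: chemical-shift-deviation mapping for
ligand titrations and NOE restraint bookkeeping.

A chemical-shift deviation (CSD) compares each amide proton resonance
between a reference state and a titration point; |delta(ppm)| converts
to Hz by multiplying with the spectrometer proton frequency in MHz.
NOE restraints are classified by sequence separation s = |i - j|:
intra-residual (0), sequential (1), medium range (2 and 3) and long
range (s >= 4, the standard NMR convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import RESTRAINT_CATEGORIES, RestraintRecord, ShiftTable

log = logging.getLogger("oligorder.nmr")

__all__ = [
    "ShiftDeviationReport",
    "RestraintSummary",
    "shift_deviation",
    "classify_restraints",
    "load_packaged_shift_table",
]


def load_packaged_shift_table() -> ShiftTable:
    """The packaged proton assignment table of the amyloid-beta 12-28
    fragment (ligand-bound state, 600.13 MHz); the ligand row carries
    residue index 0."""
    from importlib.resources import files

    from .io import read_shift_table

    return read_shift_table(str(files("oligorder.data") / "ab12_28_shifts.tsv"))


@dataclass
class ShiftDeviationReport:
    """Per-(residue, nucleus) absolute shift deviations in ppm and Hz.

    ``table`` columns: residue_index, residue_name, nucleus,
    delta_ppm, delta_hz.  ``unresolved`` lists (residue_index, nucleus)
    keys present in only one of the two input tables.
    """

    table: pd.DataFrame
    unresolved: list[tuple[int, str]]
    field_frequency_MHz: float
    reference_state: str = "reference"
    titration_point: str = "titrated"


def shift_deviation(reference: ShiftTable, titrated: ShiftTable,
                    nucleus: str | None = "HN",
                    reference_state: str = "reference",
                    titration_point: str = "titrated") -> ShiftDeviationReport:
    """Absolute chemical-shift deviations between two assignment tables.

    Only keys present in both tables are compared (symmetric in argument
    order); the rest are reported as unresolved.  ``nucleus=None``
    compares every nucleus.  The two tables must share the spectrometer
    field, else Hz values would be incomparable.
    """
    if abs(reference.field_frequency_MHz - titrated.field_frequency_MHz) > 1e-9:
        raise ValueError(
            f"field frequencies differ: {reference.field_frequency_MHz} vs {titrated.field_frequency_MHz} MHz")
    field = reference.field_frequency_MHz
    a = reference.rows
    b = titrated.rows
    if nucleus is not None:
        a = a[a["nucleus"] == nucleus]
        b = b[b["nucleus"] == nucleus]
    merged = a.merge(b, on=["residue_index", "nucleus"], how="outer",
                     suffixes=("_ref", "_tit"), indicator=True)
    matched = merged[merged["_merge"] == "both"].copy()
    unresolved = [(int(r.residue_index), str(r.nucleus))
                  for r in merged[merged["_merge"] != "both"].itertuples()]
    delta_ppm = (matched["shift_ppm_tit"] - matched["shift_ppm_ref"]).abs()
    table = pd.DataFrame({
        "residue_index": matched["residue_index"].astype(int),
        "residue_name": matched["residue_name_ref"],
        "nucleus": matched["nucleus"],
        "delta_ppm": delta_ppm,
        "delta_hz": delta_ppm * field,
    }).sort_values(["residue_index", "nucleus"]).reset_index(drop=True)
    if unresolved:
        log.info("%d unresolved (residue, nucleus) keys", len(unresolved))
    return ShiftDeviationReport(table=table, unresolved=unresolved, field_frequency_MHz=field,
                                reference_state=reference_state, titration_point=titration_point)


@dataclass
class RestraintSummary:
    """NOE restraint counts per sequence-separation category."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, category: str) -> int:
        return self.counts[category]


def classify_restraints(records: Sequence[RestraintRecord | tuple[int, int]]) -> RestraintSummary:
    """Tally restraints into intra / i+1 / i+2 / i+3 / long-range bins by
    sequence separation; the total equals the record count."""
    counts = {c: 0 for c in RESTRAINT_CATEGORIES}
    for rec in records:
        if not isinstance(rec, RestraintRecord):
            rec = RestraintRecord(int(rec[0]), int(rec[1]))
        counts[rec.category] += 1
    return RestraintSummary(counts=counts)
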
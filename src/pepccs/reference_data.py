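"""Packaged experimental/computed CCS reference tables.

Two tables for the 23 singly protonated tryptic peptides: table 1 carries the
drift-tube experimental CCS and computed values at B3LYP/6-31G(d) with no
dispersion, D3(0) and D3(BJ) dispersion; table 2 carries the 6-31G(d,p)
basis (p-polarization on hydrogens) with the two dispersion variants.  Raw
CCS values only — percent errors are always recomputed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["ReferenceRecord", "load_reference_table", "TABLE_METHODS"]

TABLE_METHODS = {
    "table1": (
        "B3LYP/6-31G(d)",
        "D3(0)-B3LYP/6-31G(d)",
        "D3(BJ)-B3LYP/6-31G(d)",
    ),
    "table2": (
        "D3(0)-B3LYP/6-31G(d,p)",
        "D3(BJ)-B3LYP/6-31G(d,p)",
    ),
}

_FILES = {
    "table1": "reference_ccs_table1.csv",
    "table2": "reference_ccs_table2.csv",
}


@dataclass(frozen=True)
class ReferenceRecord:
    """One peptide's experimental CCS plus per-method computed CCS (A^2)."""

    peptide: str
    exp_ccs: float
    method_ccs: dict[str, float]

    def __post_init__(self) -> None:
        if self.exp_ccs <= 0:
            raise ValueError("experimental CCS must be positive")


def load_reference_table(which: str) -> list[ReferenceRecord]:
    """Load the packaged reference table ``"table1"`` or ``"table2"``."""
    if which not in _FILES:
        raise KeyError(f"unknown table key {which!r}; use 'table1' or 'table2'")
    with resources.files("pepccs.data").joinpath(_FILES[which]).open() as fh:
        df = pd.read_csv(fh, comment="#")
    methods = TABLE_METHODS[which]
    records = []
    for row in df.itertuples(index=False):
        # pandas mangles punctuation in attribute names; index by position
        vals = list(row)
        peptide, exp = str(vals[0]), float(vals[1])
        method_ccs = {m: float(v) for m, v in zip(methods, vals[2:])}
        records.append(ReferenceRecord(peptide, exp, method_ccs))
    return records
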
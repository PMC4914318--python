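"""Harmonized miRNA signatures.

A :class:`Signature` is the exchange currency of the pipeline: one
differential-expression result set for one dataset, keyed by the mature
accession of the reference registry release (MIMAT-style identifiers) so
that signatures from studies written in different nomenclature eras can be
compared directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

UP = "up"
DOWN = "down"
DIRECTIONS = (UP, DOWN)

#: Canonical column order of the tabular representation.
COLUMNS = ["name", "direction", "linear_fc", "log2fc", "p", "fdr"]


class Signature:
    """A set of (accession, direction, fold-change, FDR) calls for one dataset.

    Parameters
    ----------
    table:
        DataFrame indexed by mature accession with (a subset of) the columns
        ``name``, ``direction``, ``linear_fc``, ``log2fc``, ``p``, ``fdr``.
        Only ``direction`` is mandatory; statistics missing in the source
        study are NaN.
    """

    def __init__(self, table: pd.DataFrame | None = None):
        if table is None:
            table = pd.DataFrame(columns=COLUMNS)
        table = table.copy()
        for col in COLUMNS:
            if col not in table.columns:
                table[col] = "" if col in ("name", "direction") else np.nan
        bad = set(table["direction"].dropna()) - set(DIRECTIONS) - {""}
        if bad:
            raise ValueError(f"invalid direction values: {sorted(bad)}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accessions in signature: {dups}")
        self.table = table[COLUMNS]
        self.table.index.name = "accession"

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple] | Mapping[str, str]
    ) -> "Signature":
        """Build from ``(accession, direction[, linear_fc])`` tuples or an
        ``accession -> direction`` mapping."""
        if isinstance(entries, Mapping):
            entries = [(acc, d) for acc, d in entries.items()]
        rows = {}
        for entry in entries:
            acc, direction = entry[0], entry[1]
            fc = entry[2] if len(entry) > 2 else np.nan
            rows[acc] = {"direction": direction, "linear_fc": fc}
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    @property
    def accessions(self) -> list[str]:
        return list(self.table.index)

    @property
    def directions(self) -> pd.Series:
        return self.table["direction"]

    def direction_of(self, accession: str) -> str:
        return self.table.at[accession, "direction"]

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, accession: str) -> bool:
        return accession in self.table.index

    def __eq__(self, other) -> bool:
        if not isinstance(other, Signature):
            return NotImplemented
        a = self.table.sort_index()
        b = other.table.sort_index()
        return a["direction"].equals(b["direction"]) and list(a.index) == list(
            b.index
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signature":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __repr__(self) -> str:
        n_up = int((self.table["direction"] == UP).sum())
        n_down = int((self.table["direction"] == DOWN).sum())
        return f"<Signature: {len(self)} miRNAs ({n_up} up, {n_down} down)>"
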
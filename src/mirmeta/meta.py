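"""Cross-study vote-counting meta-analysis.

Builds the study-miRNA matrix over harmonized accessions: one column per
study (a study published as several datasets is collapsed into a single
column first), cells encode the reported direction (+1 up, -1 down, 0 not
reported, ``C`` for an intra-study dataset conflict), and each miRNA gets a
frequency score per direction — simply the number of studies reporting it
in that direction.  Fold changes are never pooled: this is vote counting,
not effect-size meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .signature import DOWN, UP, Signature

CELL_UP = 1
CELL_DOWN = -1
CELL_ABSENT = 0
CELL_CONFLICT = 2  # written as "C" in the TSV form

_CELL_TO_TEXT = {CELL_UP: "1", CELL_DOWN: "-1", CELL_ABSENT: "0", CELL_CONFLICT: "C"}
_TEXT_TO_CELL = {v: k for k, v in _CELL_TO_TEXT.items()}
_DIRECTION_TO_CELL = {UP: CELL_UP, DOWN: CELL_DOWN}


@dataclass
class StudySignature:
    """All harmonized signatures published by one study.

    ``datasets`` maps dataset id -> :class:`Signature`; most studies have a
    single dataset, but a study published as several datasets contributes a
    single column to the matrix after collapsing.
    """

    study_id: str
    datasets: dict[str, Signature]

    def __post_init__(self):
        if not self.datasets:
            raise ValueError(f"study {self.study_id!r} has no datasets")

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.datasets)


def collapse_datasets(signatures: Mapping[str, Signature]) -> pd.Series:
    """Collapse a study's datasets to one direction call per miRNA.

    Any dataset reporting a miRNA makes the study report it (union); if the
    study's datasets disagree in direction the cell is a conflict.  Returns
    a Series accession -> cell code.
    """
    if not signatures:
        raise ValueError("no dataset signatures")
    directions: dict[str, set[str]] = {}
    for sig in signatures.values():
        for acc, d in sig.directions.items():
            directions.setdefault(acc, set()).add(d)
    cells = {
        acc: (_DIRECTION_TO_CELL[next(iter(ds))] if len(ds) == 1 else CELL_CONFLICT)
        for acc, ds in directions.items()
    }
    return pd.Series(cells, dtype=int).sort_index()


@dataclass
class StudyMiRNAMatrix:
    """miRNA x study direction matrix plus per-miRNA frequency scores."""

    cells: pd.DataFrame  # int codes; rows = accessions, columns = study ids
    scores: pd.DataFrame = field(init=False)  # up_count, down_count per accession

    def __post_init__(self):
        self.scores = pd.DataFrame(
            {
                "up_count": (self.cells == CELL_UP).sum(axis=1),
                "down_count": (self.cells == CELL_DOWN).sum(axis=1),
            }
        )

    @property
    def accessions(self) -> list[str]:
        return list(self.cells.index)

    @property
    def study_ids(self) -> list[str]:
        return list(self.cells.columns)

    def to_tsv(self, path: str | Path) -> None:
        text = self.cells.map(lambda c: _CELL_TO_TEXT[c])
        text.index.name = "accession"
        text.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyMiRNAMatrix":
        text = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(text.map(lambda c: _TEXT_TO_CELL[c]).astype(int))

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long form: (accession, study_id, cell)."""
        long = self.cells.stack().rename("cell").reset_index()
        long.columns = ["accession", "study_id", "cell"]
        return long


def build_matrix(studies: Sequence[StudySignature]) -> StudyMiRNAMatrix:
    """Assemble the study-miRNA matrix from per-study signatures.

    Rows are the union of accessions reported by any study; each study's
    datasets are collapsed to one column.  Duplicate study ids are an
    error.
    """
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate study id(s): {dup}")
    columns = {s.study_id: collapse_datasets(s.datasets) for s in studies}
    cells = (
        pd.DataFrame(columns)
        .fillna(CELL_ABSENT)
        .astype(int)
        .sort_index()
    )
    cells = cells[[s.study_id for s in studies]]
    return StudyMiRNAMatrix(cells)


def frequency_score(matrix: StudyMiRNAMatrix) -> dict[str, pd.DataFrame]:
    """Ranked per-direction reporting-frequency lists.

    Score = number of studies reporting the miRNA in that direction
    (conflicted studies support neither).  Each list is sorted by score
    descending, ties broken by accession, and keeps only miRNAs with a
    positive score in that direction.
    """
    out = {}
    for direction, col in ((UP, "up_count"), (DOWN, "down_count")):
        scores = matrix.scores[matrix.scores[col] > 0]
        ranked = scores.loc[
            sorted(scores.index, key=lambda a: (-scores.at[a, col], a))
        ]
        out[direction] = ranked[[col]].rename(columns={col: "score"})
    return out


def filter_min_studies(matrix: StudyMiRNAMatrix, k: int = 2) -> StudyMiRNAMatrix:
    """Keep miRNAs reported (in either direction) by at least ``k`` studies."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = matrix.scores["up_count"] + matrix.scores["down_count"]
    return StudyMiRNAMatrix(matrix.cells.loc[total >= k])


def read_study_table(path: str | Path) -> list[tuple]:
    """Read one per-study raw signature TSV (raw_name, direction[, fc])."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    entries = []
    for _, row in df.iterrows():
        if "fc" in cols and pd.notna(row.get("fc")):
            entries.append((row["raw_name"], row["direction"], float(row["fc"])))
        else:
            entries.append((row["raw_name"], row["direction"]))
    return entries


def load_studies(
    manifest_path: str | Path,
    registry,
) -> tuple[list[StudySignature], pd.DataFrame]:
    """Load and harmonize every study listed in a manifest TSV.

    The manifest has columns ``study_id``, ``dataset_id``, ``file`` (path
    relative to the manifest) and optionally platform / sample-size columns
    mirroring a studies-overview table.  Returns the harmonized studies and
    the concatenated resolution report (with study/dataset columns).
    """
    from .registry import harmonize_signature

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    studies: dict[str, dict[str, Signature]] = {}
    reports = []
    for _, row in manifest.iterrows():
        entries = read_study_table(manifest_path.parent / row["file"])
        sig, report = harmonize_signature(entries, registry)
        studies.setdefault(str(row["study_id"]), {})[str(row["dataset_id"])] = sig
        report.insert(0, "dataset_id", str(row["dataset_id"]))
        report.insert(0, "study_id", str(row["study_id"]))
        reports.append(report)
    study_list = [
        StudySignature(study_id=sid, datasets=ds) for sid, ds in studies.items()
    ]
    report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["study_id", "dataset_id", "query", "status",
                                   "candidates", "note"])
    )
    return study_list, report
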
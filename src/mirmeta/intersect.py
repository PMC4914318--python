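"""Concordant multi-dataset signature intersection.

A clinical tumor-vs-normal signature is combined with signatures from
complementary in-vitro models (for instance an oncogene-induction model and
an oncogene-inhibition model).  Because the comparison that defines "up"
differs between datasets — in an inhibition model the oncogene-active,
tumor-like state is the *control* arm — every dataset declares its
orientation explicitly, and directions are mapped onto a common
tumor-oriented axis before intersecting.  A miRNA is concordant when it
passes every dataset's own thresholds and shows the same tumor-oriented
direction everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .diffexpr import call_signature
from .signature import DOWN, UP, Signature

TUMOR_LIKE_IS_UP = "tumor_like_is_up"
TUMOR_LIKE_IS_DOWN = "tumor_like_is_down"
ORIENTATIONS = (TUMOR_LIKE_IS_UP, TUMOR_LIKE_IS_DOWN)

_FLIP = {UP: DOWN, DOWN: UP}


@dataclass
class OrientedSignature:
    """A signature plus the mapping of its directions onto the tumor axis."""

    signature: Signature
    orientation: str
    dataset_id: str = ""

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {ORIENTATIONS}, "
                f"got {self.orientation!r}"
            )

    def tumor_directions(self) -> pd.Series:
        """Per-accession direction on the tumor-oriented axis."""
        d = self.signature.directions
        if self.orientation == TUMOR_LIKE_IS_UP:
            return d
        return d.map(_FLIP)


def concordant_intersection(
    datasets: list[OrientedSignature],
) -> dict[str, list[str]]:
    """miRNAs present in every dataset with one tumor-oriented direction.

    Returns ``{"up": [...], "down": [...]}``, each list sorted by
    accession.  Requires at least two datasets; an empty dataset empties
    the intersection.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    oriented = [ds.tumor_directions() for ds in datasets]
    common = set(oriented[0].index)
    for d in oriented[1:]:
        common &= set(d.index)
    out: dict[str, list[str]] = {UP: [], DOWN: []}
    for acc in sorted(common):
        dirs = {d[acc] for d in oriented}
        if len(dirs) == 1:
            out[next(iter(dirs))].append(acc)
    return out


def apply_dataset_thresholds(
    de: pd.DataFrame,
    fc_cut: float,
    fdr_cut: float | None = None,
) -> Signature:
    """One dataset's own significance call: FC filter, plus FDR when available.

    ``fdr_cut=None`` covers datasets published with a fold-change cut only
    (no FDR column usable); delegates to :func:`mirmeta.diffexpr.call_signature`.
    """
    return call_signature(de, fc_cut=fc_cut, fdr_cut=fdr_cut)


def load_intersection_manifest(
    manifest_path: str | Path,
) -> list[OrientedSignature]:
    """Load a YAML manifest of datasets to intersect.

    Layout::

        datasets:
          - id: clinical
            signature: clinical_signature.tsv
            orientation: tumor_like_is_up
          - id: model2
            signature: model2_signature.tsv
            orientation: tumor_like_is_up   # DMSO (oncogene-active) arm is tumor-like

    Signature files are TSVs as written by :meth:`Signature.to_tsv`; paths
    are relative to the manifest.  Each entry may also carry ``fc_cut`` /
    ``fdr_cut`` documenting the thresholds its signature was called at.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    out = []
    for entry in spec["datasets"]:
        if "orientation" not in entry:
            raise ValueError(
                f"dataset {entry.get('id', '?')!r}: orientation not declared"
            )
        sig = Signature.from_tsv(manifest_path.parent / entry["signature"])
        out.append(
            OrientedSignature(
                signature=sig,
                orientation=entry["orientation"],
                dataset_id=str(entry.get("id", "")),
            )
        )
    return out


def intersection_table(
    result: dict[str, list[str]],
    datasets: list[OrientedSignature],
    registry=None,
) -> pd.DataFrame:
    """Flat output table: accession, name, direction, per-dataset linear FC."""
    rows = []
    for direction in (UP, DOWN):
        for acc in result[direction]:
            row = {
                "accession": acc,
                "name": registry.current_name(acc) if registry is not None else "",
                "direction": direction,
            }
            for ds in datasets:
                key = f"fc_{ds.dataset_id or 'dataset'}"
                row[key] = ds.signature.table.at[acc, "linear_fc"]
            rows.append(row)
    return pd.DataFrame(rows)
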
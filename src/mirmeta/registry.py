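"""miRNA registry: univocal name -> mature-accession resolution.

miRNA names drift between registry releases (arm suffixes ``-5p/-3p``
replacing the legacy star ``*`` convention, letter suffixes appearing as
paralogs are discovered, e.g. ``miR-451`` becoming ``miR-451a``).  Any
cross-study comparison therefore has to be made on the stable mature
accession (MIMAT identifier), not on the printed name.  This module parses
registry tables in the miRBase ``aliases.txt`` / ``gff3`` dialects, builds a
case-insensitive alias index over every current and historical name, and
resolves arbitrary study-table names to accessions of the reference
release.  Resolution is exact identifier tracking: an arm-less legacy name
resolves only if the registry records it as an alias — an arm is never
guessed.

The module also exposes the family / genomic-cluster / shared-precursor
grouping used to interpret coordinated deregulation of related miRNAs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .signature import DIRECTIONS, Signature

MATURE_ACCESSION_RE = re.compile(r"^MIMAT[0-9A-Z]+$")
PRECURSOR_ACCESSION_RE = re.compile(r"^MI(?!MAT)[0-9A-Z]+$")
_SPECIES_PREFIX_RE = re.compile(r"^[a-z]{3,4}-(?=(mir|let)-)")

RESOLVED = "resolved"
AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"

#: Columns of the resolution report written next to harmonized signatures.
REPORT_COLUMNS = ["query", "status", "candidates", "note"]


def normalize_name(name: str) -> str:
    """Case-fold a miRNA name and strip the species prefix.

    ``hsa-miR-451a``, ``miR-451a`` and ``MIR-451A`` all normalize to
    ``mir-451a``; a trailing ``*`` (legacy star strand) is kept, since star
    names are registry aliases in their own right.
    """
    n = name.strip().lower()
    return _SPECIES_PREFIX_RE.sub("", n)


@dataclass
class MatureRecord:
    """One mature miRNA of the reference release."""

    accession: str
    current_name: str
    previous_names: list[str] = field(default_factory=list)
    precursor_accessions: list[str] = field(default_factory=list)
    arm: str = "unspecified"  # {5p, 3p, unspecified}

    def __post_init__(self):
        if self.arm == "unspecified":
            low = self.current_name.lower()
            if low.endswith("-5p"):
                self.arm = "5p"
            elif low.endswith("-3p"):
                self.arm = "3p"

    @property
    def all_names(self) -> list[str]:
        return [self.current_name, *self.previous_names]


@dataclass
class PrecursorRecord:
    """One hairpin precursor with genomic coordinates (1-based inclusive)."""

    accession: str
    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    family_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"precursor {self.accession}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"precursor {self.accession}: invalid strand {self.strand!r}"
            )


@dataclass
class ResolutionResult:
    """Outcome of resolving one query name."""

    query: str
    status: str
    accessions: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self):
        if self.status == RESOLVED and len(self.accessions) != 1:
            raise ValueError("resolved result must carry exactly one accession")
        if self.status == UNKNOWN and self.accessions:
            raise ValueError("unknown result must carry no accessions")

    @property
    def accession(self) -> str:
        if self.status != RESOLVED:
            raise ValueError(f"{self.query!r} is {self.status}, not resolved")
        return self.accessions[0]


class MiRNARegistry:
    """Versioned mapping from every known miRNA name to mature accessions.

    Parameters
    ----------
    matures, precursors:
        Record collections; accession-uniqueness and referential integrity
        (every mature's precursors exist) are enforced at construction.
    release_label:
        Free-text label of the reference release (e.g. ``"v21"``).
    """

    def __init__(
        self,
        matures: Iterable[MatureRecord],
        precursors: Iterable[PrecursorRecord] = (),
        release_label: str = "",
    ):
        self.release_label = release_label
        self.matures: dict[str, MatureRecord] = {}
        self.precursors: dict[str, PrecursorRecord] = {}
        current_names: dict[str, str] = {}
        for rec in matures:
            if not MATURE_ACCESSION_RE.match(rec.accession):
                raise ValueError(f"malformed mature accession {rec.accession!r}")
            if rec.accession in self.matures:
                raise ValueError(f"duplicate mature accession {rec.accession!r}")
            key = normalize_name(rec.current_name)
            if key in current_names:
                raise ValueError(
                    f"current name {rec.current_name!r} maps to both "
                    f"{current_names[key]} and {rec.accession}"
                )
            current_names[key] = rec.accession
            self.matures[rec.accession] = rec
        for prec in precursors:
            if not PRECURSOR_ACCESSION_RE.match(prec.accession):
                raise ValueError(
                    f"malformed precursor accession {prec.accession!r}"
                )
            if prec.accession in self.precursors:
                raise ValueError(
                    f"duplicate precursor accession {prec.accession!r}"
                )
            self.precursors[prec.accession] = prec
        for rec in self.matures.values():
            for pa in rec.precursor_accessions:
                if pa not in self.precursors:
                    raise ValueError(
                        f"mature {rec.accession} references unknown precursor {pa}"
                    )
        self.alias_index: dict[str, set[str]] = {}
        for rec in self.matures.values():
            for name in rec.all_names:
                self.alias_index.setdefault(normalize_name(name), set()).add(
                    rec.accession
                )

    def __len__(self) -> int:
        return len(self.matures)

    def __contains__(self, accession: str) -> bool:
        return accession in self.matures

    def current_name(self, accession: str) -> str:
        return self.matures[accession].current_name

    def resolve(self, name: str) -> ResolutionResult:
        return resolve_name(name, self)

    def __repr__(self) -> str:
        return (
            f"<MiRNARegistry {self.release_label or '(unlabelled)'}: "
            f"{len(self.matures)} matures, {len(self.precursors)} precursors>"
        )


def _parse_gff_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_registry(
    alias_table: str | Path,
    precursor_table: str | Path,
    release_label: str = "",
) -> MiRNARegistry:
    """Parse an aliases table plus a precursor coordinate table.

    The alias table is 2-column TSV in the miRBase ``aliases.txt`` dialect:
    accession, then a semicolon-separated (and -terminated) name list whose
    LAST entry is the current name; earlier entries are historical names.
    The precursor table is GFF3-like, with ``miRNA_primary_transcript``
    lines carrying ``ID=<MI accession>;Name=...;family=...`` and ``miRNA``
    lines carrying ``ID=<MIMAT accession>;...;Derives_from=<MI accession>``
    to link matures to their hairpins.
    """
    alias_rows: dict[str, list[str]] = {}
    with open(alias_table) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{alias_table}:{lineno}: expected 2 tab-separated fields"
                )
            accession, namelist = parts
            if not MATURE_ACCESSION_RE.match(accession):
                raise ValueError(
                    f"{alias_table}:{lineno}: malformed accession {accession!r}"
                )
            if accession in alias_rows:
                raise ValueError(
                    f"{alias_table}:{lineno}: duplicate accession {accession!r}"
                )
            names = [n.strip() for n in namelist.split(";") if n.strip()]
            if not names:
                raise ValueError(
                    f"{alias_table}:{lineno}: empty name list for {accession}"
                )
            alias_rows[accession] = names
    if not alias_rows:
        raise ValueError(f"{alias_table}: no mature records")

    precursors: list[PrecursorRecord] = []
    mature_precursors: dict[str, list[str]] = {}
    with open(precursor_table) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{precursor_table}:{lineno}: expected 9 GFF columns"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = cols
            attributes = _parse_gff_attributes(attrs)
            if feature == "miRNA_primary_transcript":
                acc = attributes.get("ID", "")
                if not PRECURSOR_ACCESSION_RE.match(acc):
                    raise ValueError(
                        f"{precursor_table}:{lineno}: malformed precursor "
                        f"accession {acc!r}"
                    )
                precursors.append(
                    PrecursorRecord(
                        accession=acc,
                        name=attributes.get("Name", acc),
                        chromosome=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        family_id=attributes.get("family", ""),
                    )
                )
            elif feature == "miRNA":
                acc = attributes.get("ID", "")
                parent = attributes.get("Derives_from", "")
                if acc and parent:
                    mature_precursors.setdefault(acc, []).append(parent)

    matures = [
        MatureRecord(
            accession=acc,
            current_name=names[-1],
            previous_names=names[:-1],
            precursor_accessions=mature_precursors.get(acc, []),
        )
        for acc, names in alias_rows.items()
    ]
    return MiRNARegistry(matures, precursors, release_label=release_label)


def resolve_name(name: str, registry: MiRNARegistry) -> ResolutionResult:
    """Resolve one printed miRNA name to mature accession(s).

    Lookup is case-insensitive and species-prefix-agnostic, strictly through
    the recorded alias index.  One hit resolves; several hits (a name reused
    across accessions in some historical release) are returned as ambiguous
    with all candidates; no hit is unknown.
    """
    if not name or not name.strip():
        raise ValueError("empty query name")
    hits = sorted(registry.alias_index.get(normalize_name(name), ()))
    if len(hits) == 1:
        return ResolutionResult(name, RESOLVED, hits)
    if len(hits) > 1:
        return ResolutionResult(
            name, AMBIGUOUS, hits, note=f"{len(hits)} candidate accessions"
        )
    return ResolutionResult(name, UNKNOWN, [], note="no alias match")


def harmonize_signature(
    entries: Sequence[tuple],
    registry: MiRNARegistry,
) -> tuple[Signature, pd.DataFrame]:
    """Map raw study-table entries onto registry accessions.

    ``entries`` are ``(raw_name, direction[, fold_change])`` tuples with
    direction in {up, down}.  Entries resolving to the same accession with
    the same direction are merged (the largest-magnitude fold change is
    kept); ambiguous and unknown names are excluded from the signature but
    listed in the report; an accession reported in both directions within
    the same study is an intra-study conflict — excluded and reported.

    Returns the harmonized :class:`Signature` and the resolution report
    (columns: query, status, candidates, note).
    """
    report_rows: list[dict] = []
    per_accession: dict[str, dict] = {}
    for entry in entries:
        raw_name, direction = entry[0], entry[1]
        fc = float(entry[2]) if len(entry) > 2 and entry[2] is not None else None
        if direction not in DIRECTIONS:
            raise ValueError(f"invalid direction {direction!r} for {raw_name!r}")
        res = resolve_name(raw_name, registry)
        report_rows.append(
            {
                "query": raw_name,
                "status": res.status,
                "candidates": ";".join(res.accessions),
                "note": res.note,
            }
        )
        if res.status != RESOLVED:
            continue
        acc = res.accession
        slot = per_accession.setdefault(acc, {"directions": set(), "fc": None})
        slot["directions"].add(direction)
        if fc is not None and (
            slot["fc"] is None or abs(fc) > abs(slot["fc"])
        ):
            slot["fc"] = fc

    rows = {}
    for acc in sorted(per_accession):
        slot = per_accession[acc]
        if len(slot["directions"]) > 1:
            report_rows.append(
                {
                    "query": registry.current_name(acc),
                    "status": "intra-study conflict",
                    "candidates": acc,
                    "note": "reported in both directions; excluded",
                }
            )
            continue
        rows[acc] = {
            "name": registry.current_name(acc),
            "direction": next(iter(slot["directions"])),
            "linear_fc": slot["fc"],
        }
    report = pd.DataFrame(report_rows, columns=REPORT_COLUMNS)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return Signature(table), report


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_mirnas(
    accessions: Sequence[str],
    registry: MiRNARegistry,
    cluster_window_bp: int = 10000,
) -> pd.DataFrame:
    """Partition mature miRNAs into family / genomic-cluster / shared-precursor groups.

    Three independent groupings over the queried accessions:

    * ``family`` — matures whose precursors share a non-empty family label
      (sequence similarity, typically in the seed region);
    * ``cluster`` — matures whose precursors lie on the same chromosome and
      strand with inter-precursor gaps of at most ``cluster_window_bp``
      (transitive closure — polycistronic neighbourhoods);
    * ``precursor`` — matures derived from the same hairpin (the ``-5p/-3p``
      pair of one precursor).

    Only groups with at least two member matures are reported.  Returns a
    tidy table with columns ``group_type``, ``group_id``, ``accession``.
    """
    for acc in accessions:
        if acc not in registry.matures:
            raise ValueError(f"unknown accession {acc!r}")
    accessions = sorted(set(accessions))

    rows: list[dict] = []

    # family groups, via precursor family labels
    family_members: dict[str, set[str]] = {}
    for acc in accessions:
        for pa in registry.matures[acc].precursor_accessions:
            fam = registry.precursors[pa].family_id
            if fam:
                family_members.setdefault(fam, set()).add(acc)
    for fam in sorted(family_members):
        members = sorted(family_members[fam])
        if len(members) >= 2:
            rows.extend(
                {"group_type": "family", "group_id": fam, "accession": m}
                for m in members
            )

    # genomic clusters: union-find over precursors of the queried matures
    prec_of_query: dict[str, set[str]] = {}
    for acc in accessions:
        for pa in registry.matures[acc].precursor_accessions:
            prec_of_query.setdefault(pa, set()).add(acc)
    precs = sorted(prec_of_query)
    uf = _UnionFind(precs)
    by_locus: dict[tuple[str, str], list[str]] = {}
    for pa in precs:
        p = registry.precursors[pa]
        by_locus.setdefault((p.chromosome, p.strand), []).append(pa)
    for locus_precs in by_locus.values():
        ordered = sorted(
            locus_precs, key=lambda a: (registry.precursors[a].start, a)
        )
        # sweep with running max end so a long hairpin links across shorter ones
        anchor, max_end = ordered[0], registry.precursors[ordered[0]].end
        for cur in ordered[1:]:
            rec = registry.precursors[cur]
            if max(rec.start - max_end, 0) <= cluster_window_bp:
                uf.union(anchor, cur)
            else:
                anchor = cur
            max_end = max(max_end, rec.end)
    components: dict[str, set[str]] = {}
    for pa in precs:
        components.setdefault(uf.find(pa), set()).add(pa)
    for comp_precs in components.values():
        members = sorted(set().union(*(prec_of_query[pa] for pa in comp_precs)))
        if len(members) >= 2 and len(comp_precs) >= 2:
            p0 = registry.precursors[min(comp_precs)]
            start = min(registry.precursors[pa].start for pa in comp_precs)
            end = max(registry.precursors[pa].end for pa in comp_precs)
            gid = f"{p0.chromosome}({p0.strand}):{start}-{end}"
            rows.extend(
                {"group_type": "cluster", "group_id": gid, "accession": m}
                for m in members
            )

    # shared-precursor groups
    for pa in precs:
        members = sorted(prec_of_query[pa])
        if len(members) >= 2:
            rows.extend(
                {"group_type": "precursor", "group_id": pa, "accession": m}
                for m in members
            )

    out = pd.DataFrame(rows, columns=["group_type", "group_id", "accession"])
    return out.sort_values(
        ["group_type", "group_id", "accession"], ignore_index=True
    )
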
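"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study conditions of a cross-study miRNA
deregulation analysis without any download:

* a two-release registry in the aliases/gff3 dialects, with planted
  renames (arm-less, star-form and letter-less legacy names), optional
  alias collisions, shared-precursor mature pairs and genomic clusters;
* a discovery-scale log2 expression matrix (19 tumor vs 5 normal by
  default) with planted differentially expressed miRNAs on Gaussian
  log2-scale noise and platform-style detection flags;
* per-sample isoform quantification files at validation scale (100 tumor
  vs 12 normal by default, a speed-scaled stand-in for a 499/59 cohort)
  whose counts are multinomial reads split over 1-5 isoform records, a
  fraction keyed by old-release accessions so aggregation must consult the
  release map;
* a 15-study corpus of signature tables written in era-specific
  nomenclature with a planted consensus set, one study emitted as three
  datasets to exercise within-study collapsing.

Identical spec + seed give byte-identical output files.  Each generator
draws from its own stream seeded from ``spec.seed`` plus a fixed offset,
so the stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffexpr import ExpressionMatrix
from .registry import MiRNARegistry, load_registry
from .signature import DOWN, UP

_STREAM_OFFSETS = {"registry": 1, "expression": 2, "isoform": 3, "studies": 4,
                   "blocks": 5}


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with the default study conditions.

    Discovery defaults mirror a 19-tumor / 5-normal array design with 500
    candidate miRNAs of which 18 are truly deregulated at |log2FC| = 2 on
    sigma = 0.5 log2 noise; the validation arm is a 100/12 cohort (a
    speed-scaled 499/59); the literature corpus has 15 studies with a
    20% per-study dropout of consensus miRNAs.
    """

    seed: int = 0
    # registry
    n_mirnas: int = 500
    rename_fraction: float = 0.5
    shared_precursor_fraction: float = 0.3
    cluster_fraction: float = 0.15
    family_group_count: int = 10
    collision_count: int = 0
    cluster_window_bp: int = 10000
    # discovery expression matrix
    n_tumor: int = 19
    n_normal: int = 5
    n_de: int = 18
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    detection_log2_cutoff: float = 5.0
    # validation isoform files
    n_validation_tumor: int = 100
    n_validation_normal: int = 12
    n_isoform_mirnas: int = 200
    n_isoform_shifted: int = 10
    isoform_shift_log2: float = -2.0
    old_accession_fraction: float = 0.3
    unmapped_fraction: float = 0.02
    reads_per_sample: int = 1_000_000
    # study corpus
    n_studies: int = 15
    n_consensus_up: int = 4
    n_consensus_down: int = 6
    study_noise_rate: float = 0.2
    era_fraction_old: float = 0.5
    multi_dataset_study: bool = True
    plant_conflict: bool = False

    def __post_init__(self):
        if self.n_de > self.n_mirnas:
            raise ValueError("n_de cannot exceed n_mirnas")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("n_mirnas", "n_tumor", "n_normal", "n_studies"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.study_noise_rate <= 1:
            raise ValueError("study_noise_rate must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.seed * 8 + _STREAM_OFFSETS[stream])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def mature_accession(i: int) -> str:
    """Deterministic synthetic mature accession for miRNA index ``i``."""
    return f"MIMAT{9000000 + i:07d}"


def precursor_accession(j: int) -> str:
    return f"MI{9000000 + j:07d}"


def old_accession(i: int) -> str:
    """Source-release accession of miRNA ``i`` (pre-reannotation key)."""
    return f"MIMAT{8000000 + i:07d}"


@dataclass
class RegistryTruth:
    """What the registry generator planted."""

    renames: pd.DataFrame  # columns: accession, legacy_name, current_name
    collisions: list[tuple[str, str, str]]  # (shared name, accession_a, accession_b)
    shared_precursor_pairs: list[tuple[str, str]]
    cluster_precursor_pairs: list[tuple[str, str]]
    alias_lines: list[str]
    gff_lines: list[str]


def make_registry(
    spec: SimulationSpec, outdir: str | Path | None = None
) -> tuple[MiRNARegistry, RegistryTruth]:
    """Generate a two-era registry and (optionally) write its tables.

    Matures are created precursor-by-precursor: a fraction of hairpins
    yield a -5p/-3p pair (shared precursor), the rest a single mature.  A
    ``rename_fraction`` of matures carry a legacy previous name: the
    dominant arm of a pair gets the arm-less name, the minor arm the star
    form, and singles a letter-less name (the ``miR-451`` -> ``miR-451a``
    pattern).  Precursors are laid down along synthetic chromosomes; with
    probability ``cluster_fraction`` a hairpin is placed within the cluster
    window of its predecessor on the same strand.
    """
    rng = spec.rng("registry")
    matures = []  # (accession, [previous..., current], precursor_accession)
    precursors = []  # (accession, name, chrom, start, end, strand, family)
    shared_pairs: list[tuple[str, str]] = []
    cluster_pairs: list[tuple[str, str]] = []
    rename_rows = []

    chrom_idx, pos, strand = 1, 1, "+"
    prev_prec: str | None = None
    i = 0  # mature index
    j = 0  # precursor index
    while i < spec.n_mirnas:
        base = 9000 + j
        pair = (
            rng.random() < spec.shared_precursor_fraction
            and i + 1 < spec.n_mirnas
        )
        # genomic placement
        clustered = j > 0 and rng.random() < spec.cluster_fraction
        if clustered:
            gap = int(rng.integers(50, max(spec.cluster_window_bp // 2, 51)))
        else:
            gap = int(rng.integers(spec.cluster_window_bp * 10,
                                   spec.cluster_window_bp * 100))
            strand = "+" if rng.random() < 0.5 else "-"
            if pos > 5_000_000 * chrom_idx:
                chrom_idx += 1
        start = pos + gap
        end = start + int(rng.integers(60, 110))
        pos = end
        prec_acc = precursor_accession(j)
        prec_name = f"hsa-mir-{base}"
        precursors.append(
            [prec_acc, prec_name, f"chrS{chrom_idx}", start, end, strand, ""]
        )
        if clustered and prev_prec is not None:
            cluster_pairs.append((prev_prec, prec_acc))
        prev_prec = prec_acc

        renamed = rng.random() < spec.rename_fraction
        if pair:
            acc5, acc3 = mature_accession(i), mature_accession(i + 1)
            cur5, cur3 = f"hsa-miR-{base}-5p", f"hsa-miR-{base}-3p"
            prev5 = [f"hsa-miR-{base}"] if renamed else []
            prev3 = [f"hsa-miR-{base}*"] if renamed else []
            matures.append((acc5, prev5 + [cur5], prec_acc))
            matures.append((acc3, prev3 + [cur3], prec_acc))
            shared_pairs.append((acc5, acc3))
            if renamed:
                rename_rows.append((acc5, prev5[0], cur5))
                rename_rows.append((acc3, prev3[0], cur3))
            i += 2
        else:
            acc = mature_accession(i)
            if renamed:
                cur = f"hsa-miR-{base}a"
                prev = [f"hsa-miR-{base}"]
                rename_rows.append((acc, prev[0], cur))
            else:
                cur = f"hsa-miR-{base}"
                prev = []
            matures.append((acc, prev + [cur], prec_acc))
            i += 1
        j += 1

    # family labels over consecutive precursor groups
    n_prec = len(precursors)
    fam_starts = rng.choice(
        max(n_prec - 3, 1),
        size=min(spec.family_group_count, max(n_prec // 4, 1)),
        replace=False,
    )
    for g, s in enumerate(sorted(fam_starts)):
        fam = f"mipf-syn-{g:03d}"
        for rec in precursors[s : s + int(rng.integers(2, 4))]:
            if rec[6] == "":
                rec[6] = fam

    # planted alias collisions: one fake legacy name shared by two accessions
    collisions: list[tuple[str, str, str]] = []
    if spec.collision_count > 0:
        idx = rng.choice(len(matures), size=2 * spec.collision_count, replace=False)
        for c in range(spec.collision_count):
            a, b = int(idx[2 * c]), int(idx[2 * c + 1])
            shared = f"hsa-miR-7{c:03d}-legacy"
            matures[a] = (matures[a][0], [shared] + matures[a][1], matures[a][2])
            matures[b] = (matures[b][0], [shared] + matures[b][1], matures[b][2])
            collisions.append((shared, matures[a][0], matures[b][0]))

    alias_lines = [f"{acc}\t{';'.join(names)};" for acc, names, _ in matures]
    gff_lines = ["##gff-version 3"]
    for acc, name, chrom, start, end, strand_, fam in precursors:
        attrs = f"ID={acc};Name={name}"
        if fam:
            attrs += f";family={fam}"
        gff_lines.append(
            f"{chrom}\tsynthetic\tmiRNA_primary_transcript\t{start}\t{end}"
            f"\t.\t{strand_}\t.\t{attrs}"
        )
    prec_coord = {p[0]: p for p in precursors}
    for acc, names, prec_acc in matures:
        _, _, chrom, start, end, strand_, _ = prec_coord[prec_acc]
        attrs = f"ID={acc};Name={names[-1]};Derives_from={prec_acc}"
        gff_lines.append(
            f"{chrom}\tsynthetic\tmiRNA\t{start}\t{end}\t.\t{strand_}\t.\t{attrs}"
        )

    truth = RegistryTruth(
        renames=pd.DataFrame(
            rename_rows, columns=["accession", "legacy_name", "current_name"]
        ),
        collisions=collisions,
        shared_precursor_pairs=shared_pairs,
        cluster_precursor_pairs=cluster_pairs,
        alias_lines=alias_lines,
        gff_lines=gff_lines,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "aliases.txt").write_text("\n".join(alias_lines) + "\n")
        (outdir / "precursors.gff3").write_text("\n".join(gff_lines) + "\n")
        registry = load_registry(
            outdir / "aliases.txt", outdir / "precursors.gff3", "synthetic-v2"
        )
    else:
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            (Path(td) / "aliases.txt").write_text("\n".join(alias_lines) + "\n")
            (Path(td) / "precursors.gff3").write_text("\n".join(gff_lines) + "\n")
            registry = load_registry(
                Path(td) / "aliases.txt",
                Path(td) / "precursors.gff3",
                "synthetic-v2",
            )
    return registry, truth


@dataclass
class ExpressionTruth:
    de: dict[str, str]  # accession -> planted direction


def make_expression(
    spec: SimulationSpec, outdir: str | Path | None = None
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Discovery-scale log2 matrix with planted group effects.

    Row baselines are uniform on [4, 12] log2 units (planted rows on
    [6, 12] so real signals sit above the detection floor, as expressed
    miRNAs do); tumor columns of planted rows are shifted by
    +/- ``effect_log2fc``; i.i.d. Gaussian noise of sd ``noise_sd`` is
    added everywhere.  Detection flags are simply value > detection
    cutoff, emulating a platform's is-detected call.
    """
    rng = spec.rng("expression")
    accessions = [mature_accession(i) for i in range(spec.n_mirnas)]
    samples = [f"T{i + 1:03d}" for i in range(spec.n_tumor)] + [
        f"N{i + 1:03d}" for i in range(spec.n_normal)
    ]
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}

    de_idx = rng.choice(spec.n_mirnas, size=spec.n_de, replace=False)
    signs = np.where(rng.random(spec.n_de) < 0.5, 1.0, -1.0)
    baseline = rng.uniform(4, 12, size=spec.n_mirnas)
    baseline[de_idx] = rng.uniform(6, 12, size=spec.n_de)

    values = np.tile(baseline[:, None], (1, len(samples)))
    effect = np.zeros(spec.n_mirnas)
    effect[de_idx] = signs * spec.effect_log2fc
    values[:, : spec.n_tumor] += effect[:, None]
    values += rng.normal(0, spec.noise_sd, size=values.shape)

    vdf = pd.DataFrame(values, index=accessions, columns=samples)
    vdf.index.name = "accession"
    detected = vdf > spec.detection_log2_cutoff
    matrix = ExpressionMatrix(values=vdf, sample_groups=groups, detected=detected)
    truth = ExpressionTruth(
        de={
            accessions[int(i)]: (UP if s > 0 else DOWN)
            for i, s in zip(de_idx, signs)
        }
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        matrix.to_tsv(
            outdir / "expression.tsv",
            outdir / "detection.tsv",
            outdir / "groups.tsv",
        )
    return matrix, truth


@dataclass
class IsoformTruth:
    shifts: dict[str, float]  # current accession -> planted tumor log2 shift
    counts: pd.DataFrame  # planted per-(accession, sample) mature counts
    unmapped_old_accessions: list[str]
    focal_accession: str  # the stratified miRNA
    aggressive_stratum: str
    strata: dict[str, str]  # sample -> stratum label


STRATA = ["classical", "follicular", "tall_cell"]


def make_isoform_files(
    spec: SimulationSpec, outdir: str | Path | None = None
) -> tuple[pd.DataFrame, dict[str, str], IsoformTruth]:
    """Validation-scale isoform records with planted RPM-scale shifts.

    Per-sample totals are multinomial over lognormal abundance weights;
    planted rows have their tumor weight multiplied by
    ``2**isoform_shift_log2``.  Each (sample, mature) count is split over
    1-5 isoform records.  A fraction of matures are keyed by old-release
    accessions (mapped back by the returned release map) and a small
    fraction is left out of the map entirely to exercise the unmapped
    report.  Tumor samples carry histology-like strata; the focal shifted
    miRNA has an extra shift in the "aggressive" stratum.

    Returns ``(records, release_map, truth)``; ``records`` is the pooled
    3-column table (sample_id, mature_accession, read_count).
    """
    rng = spec.rng("isoform")
    n = spec.n_isoform_mirnas
    current = [mature_accession(i) for i in range(n)]
    tumor = [f"V-T{i + 1:03d}" for i in range(spec.n_validation_tumor)]
    normal = [f"V-N{i + 1:03d}" for i in range(spec.n_validation_normal)]
    samples = tumor + normal
    strata = {s: STRATA[int(rng.integers(len(STRATA)))] for s in tumor}
    strata.update({s: "normal" for s in normal})
    aggressive = "tall_cell"

    shifted_idx = rng.choice(n, size=spec.n_isoform_shifted, replace=False)
    focal = current[int(shifted_idx[0])] if spec.n_isoform_shifted else current[0]
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=n)

    # accession keying: old-release ids for a fraction, some unmapped
    n_old = int(round(spec.old_accession_fraction * n))
    old_rows = rng.choice(n, size=n_old, replace=False)
    key_of = {i: mature_accession(i) for i in range(n)}
    release_map = {mature_accession(i): mature_accession(i) for i in range(n)}
    for i in old_rows:
        key_of[int(i)] = old_accession(int(i))
        del release_map[mature_accession(int(i))]
        release_map[old_accession(int(i))] = mature_accession(int(i))
    n_unmapped = int(round(spec.unmapped_fraction * n))
    unmapped_old = []
    if n_unmapped:
        candidates = [int(i) for i in range(n) if int(i) not in set(map(int, shifted_idx))]
        drop = rng.choice(len(candidates), size=n_unmapped, replace=False)
        for d in drop:
            i = candidates[int(d)]
            release_map.pop(key_of[i])
            unmapped_old.append(key_of[i])

    count_rows = {}
    records = []
    shift_factor = 2.0 ** spec.isoform_shift_log2
    for s in samples:
        w = weights.copy()
        if s in set(tumor):
            w[shifted_idx] *= shift_factor
            if spec.n_isoform_shifted and strata[s] == aggressive:
                w[int(shifted_idx[0])] *= 0.5  # extra -1 log2 on the focal miRNA
        p = w / w.sum()
        counts = rng.multinomial(spec.reads_per_sample, p)
        count_rows[s] = counts
        for i in range(n):
            c = int(counts[i])
            if c == 0:
                continue
            n_iso = int(rng.integers(1, 6))
            if n_iso == 1 or c < n_iso:
                splits = [c]
            else:
                splits = rng.multinomial(c, np.ones(n_iso) / n_iso)
                splits = [int(x) for x in splits if x > 0]
            for part in splits:
                records.append((s, key_of[i], int(part)))

    records_df = pd.DataFrame(
        records, columns=["sample_id", "mature_accession", "read_count"]
    )
    counts_df = pd.DataFrame(count_rows, index=current)
    counts_df.index.name = "accession"
    truth = IsoformTruth(
        shifts={current[int(i)]: spec.isoform_shift_log2 for i in shifted_idx},
        counts=counts_df,
        unmapped_old_accessions=sorted(unmapped_old),
        focal_accession=focal,
        aggressive_stratum=aggressive,
        strata=strata,
    )
    if outdir is not None:
        outdir = Path(outdir)
        iso_dir = outdir / "isoforms"
        iso_dir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            sub = records_df[records_df["sample_id"] == s]
            sub.to_csv(iso_dir / f"{s}.isoforms.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(release_map.items()), columns=["old", "current"]
        ).to_csv(outdir / "release_map.tsv", sep="\t", index=False)
        pd.Series(strata, name="stratum").rename_axis("sample").to_csv(
            outdir / "strata.tsv", sep="\t"
        )
    return records_df, release_map, truth


@dataclass
class StudyCorpusTruth:
    consensus: dict[str, str]  # accession -> direction
    top_down_accession: str
    reported: dict[str, dict[str, str]]  # study_id -> accession -> direction
    eras: dict[str, str]


def make_study_signatures(
    spec: SimulationSpec,
    registry: MiRNARegistry,
    registry_truth: RegistryTruth,
    outdir: str | Path | None = None,
) -> tuple[dict[str, dict[str, list[tuple]]], pd.DataFrame, StudyCorpusTruth]:
    """A literature corpus with a planted consensus set.

    A consensus of ``n_consensus_up + n_consensus_down`` miRNAs is chosen;
    every study reports each consensus miRNA with probability
    ``1 - study_noise_rate`` — except the designated most-frequent
    down-regulated miRNA (the smallest consensus accession), which every
    study reports, encoding "most frequently reported" as planted
    structure.  Studies additionally report 2-5 random non-consensus
    miRNAs each.  Old-era studies print legacy names where the registry
    records one; the first study is emitted as three datasets.

    Returns ``(tables, manifest, truth)`` where ``tables`` maps
    study_id -> dataset_id -> raw (name, direction, fc) entries.
    """
    rng = spec.rng("studies")
    accs = sorted(registry.matures)
    n_cons = spec.n_consensus_up + spec.n_consensus_down
    cons_idx = rng.choice(len(accs), size=n_cons, replace=False)
    cons_accs = sorted(accs[int(i)] for i in cons_idx)
    # smallest accession is the designated most-frequent down miRNA
    top_down = cons_accs[0]
    rest = [a for a in cons_accs if a != top_down]
    rng.shuffle(rest)
    consensus = {top_down: DOWN}
    for a in rest[: spec.n_consensus_up]:
        consensus[a] = UP
    for a in rest[spec.n_consensus_up :]:
        consensus[a] = DOWN

    legacy = dict(
        zip(registry_truth.renames["accession"], registry_truth.renames["legacy_name"])
    )
    collision_names = {name for name, _, _ in registry_truth.collisions}

    def printed_name(acc: str, era: str) -> str:
        name = legacy.get(acc) if era == "old" and acc in legacy else None
        name = name if name and name not in collision_names else None
        return name or registry.current_name(acc)

    tables: dict[str, dict[str, list[tuple]]] = {}
    reported: dict[str, dict[str, str]] = {}
    eras: dict[str, str] = {}
    noise_pool = [a for a in accs if a not in consensus]
    for s in range(spec.n_studies):
        study_id = f"study{s + 1:02d}"
        era = "old" if rng.random() < spec.era_fraction_old else "new"
        eras[study_id] = era
        study_report: dict[str, str] = {}
        for acc, direction in consensus.items():
            if acc == top_down or rng.random() >= spec.study_noise_rate:
                study_report[acc] = direction
        n_noise = int(rng.integers(2, 6))
        for i in rng.choice(len(noise_pool), size=n_noise, replace=False):
            acc = noise_pool[int(i)]
            study_report.setdefault(acc, UP if rng.random() < 0.5 else DOWN)
        reported[study_id] = study_report

        entries = [
            (printed_name(acc, era), d, float(np.round(rng.uniform(1.5, 8.0), 2)))
            for acc, d in sorted(study_report.items())
        ]
        if s == 0 and spec.multi_dataset_study:
            datasets: dict[str, list[tuple]] = {"ds1": [], "ds2": [], "ds3": []}
            ds_ids = list(datasets)
            for k, entry in enumerate(entries):
                home = ds_ids[k % 3]
                datasets[home].append(entry)
                for other in ds_ids:
                    if other != home and rng.random() < 0.4:
                        datasets[other].append(entry)
            if spec.plant_conflict and entries:
                name, d, fc = entries[0]
                flipped = (name, DOWN if d == UP else UP, fc)
                datasets["ds2"] = [
                    flipped if e[0] == name else e for e in datasets["ds2"]
                ]
                if all(e[0] != name for e in datasets["ds2"]):
                    datasets["ds2"].append(flipped)
            tables[study_id] = datasets
        else:
            tables[study_id] = {"ds1": entries}

    manifest_rows = []
    for study_id, datasets in tables.items():
        for ds_id, entries in datasets.items():
            manifest_rows.append(
                {
                    "study_id": study_id,
                    "dataset_id": ds_id,
                    "file": f"{study_id}_{ds_id}.tsv",
                    "platform": "synthetic",
                    "n_tumor": int(rng.integers(5, 100)),
                    "n_normal": int(rng.integers(3, 20)),
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    truth = StudyCorpusTruth(
        consensus=consensus,
        top_down_accession=top_down,
        reported=reported,
        eras=eras,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for study_id, datasets in tables.items():
            for ds_id, entries in datasets.items():
                pd.DataFrame(
                    entries, columns=["raw_name", "direction", "fc"]
                ).to_csv(outdir / f"{study_id}_{ds_id}.tsv", sep="\t", index=False)
        manifest.to_csv(outdir / "studies_manifest.tsv", sep="\t", index=False)
    return tables, manifest, truth


@dataclass
class BlockTruth:
    blocks: dict[str, int]  # sample -> block id


def make_block_matrix(
    spec: SimulationSpec,
    n_samples: int = 24,
    n_features: int = 50,
    block_shift: float = 1.0,
) -> tuple[pd.DataFrame, BlockTruth]:
    """Two-block sample matrix for clustering recovery tests.

    Block-2 samples carry a signature-like pattern: half the features are
    shifted up by ``block_shift`` log2 units and half down (a uniform shift
    would be invisible to correlation distance), on noise of sd
    ``spec.noise_sd``.
    """
    rng = spec.rng("blocks")
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    blocks = {s: (1 if i < n_samples // 2 else 2) for i, s in enumerate(samples)}
    base = rng.uniform(4, 12, size=n_features)
    x = np.tile(base[:, None], (1, n_samples))
    signs = np.where(rng.permutation(n_features) < n_features // 2, 1.0, -1.0)
    for i, s in enumerate(samples):
        if blocks[s] == 2:
            x[:, i] += signs * block_shift
    x += rng.normal(0, spec.noise_sd, size=x.shape)
    df = pd.DataFrame(x, index=[f"feat{i:03d}" for i in range(n_features)],
                      columns=samples)
    return df, BlockTruth(blocks=blocks)


@dataclass
class SimulationResult:
    spec: SimulationSpec
    registry: MiRNARegistry
    registry_truth: RegistryTruth
    expression: ExpressionMatrix
    expression_truth: ExpressionTruth
    isoform_records: pd.DataFrame
    release_map: dict[str, str]
    isoform_truth: IsoformTruth
    study_tables: dict[str, dict[str, list[tuple]]]
    study_manifest: pd.DataFrame
    study_truth: StudyCorpusTruth


def simulate_all(
    spec: SimulationSpec, outdir: str | Path | None = None
) -> SimulationResult:
    """Run every generator and (optionally) write all files under ``outdir``."""
    registry, reg_truth = make_registry(spec, outdir)
    expression, expr_truth = make_expression(spec, outdir)
    records, release_map, iso_truth = make_isoform_files(spec, outdir)
    tables, manifest, study_truth = make_study_signatures(
        spec, registry, reg_truth, outdir
    )
    result = SimulationResult(
        spec=spec,
        registry=registry,
        registry_truth=reg_truth,
        expression=expression,
        expression_truth=expr_truth,
        isoform_records=records,
        release_map=release_map,
        isoform_truth=iso_truth,
        study_tables=tables,
        study_manifest=manifest,
        study_truth=study_truth,
    )
    self_audit(result)
    return result


def self_audit(result: SimulationResult) -> None:
    """Check that the emitted ground truth matches the emitted data.

    Raises AssertionError on any mismatch; called automatically by
    :func:`simulate_all`.
    """
    reg = result.registry
    # every planted rename resolves to its generating accession by both names
    for _, row in result.registry_truth.renames.iterrows():
        for name in (row["legacy_name"], row["current_name"]):
            res = reg.resolve(name)
            assert res.status == "resolved" and res.accession == row["accession"], (
                f"rename audit failed for {name!r}"
            )
    # planted collisions are ambiguous
    for name, a, b in result.registry_truth.collisions:
        res = reg.resolve(name)
        assert res.status == "ambiguous" and set(res.accessions) >= {a, b}
    # planted DE accessions exist in the matrix
    assert set(result.expression_truth.de) <= set(result.expression.values.index)
    # isoform records conserve the planted per-(sample, mature) counts
    grouped = result.isoform_records.groupby(
        ["sample_id", "mature_accession"]
    )["read_count"].sum()
    total_records = int(result.isoform_records["read_count"].sum())
    total_truth = int(result.isoform_truth.counts.to_numpy().sum())
    assert total_records == total_truth, "isoform read totals diverge from truth"
    assert (grouped >= 0).all()
    # every consensus miRNA the truth marks reported is in the study tables
    for study_id, report in result.study_truth.reported.items():
        printed = {
            entry[0]
            for ds in result.study_tables[study_id].values()
            for entry in ds
        }
        for acc in report:
            names = set(reg.matures[acc].all_names)
            assert printed & names, f"{study_id}: {acc} missing from tables"
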
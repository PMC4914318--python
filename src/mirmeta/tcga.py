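"""TCGA-style miRNA-seq processing and validation statistics.

Level-3-like isoform quantification files carry several records per
(sample, mature accession) pair.  The stage implemented here sums those
read counts to one count per mature accession, reannotates source-release
accessions to the reference release through an accession map (records that
do not map are excluded and reported, never carried under stale ids),
normalizes to reads-per-million over the aggregated matures, log2-transforms
after replacing zeros with the minimum non-null value, and runs the
validation statistics: two-group Wilcoxon + Benjamini–Hochberg over a
signature subset, and Kruskal–Wallis plus pairwise Wilcoxon tests across
clinical strata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, rank_sum_test

ISOFORM_COLUMNS = ["sample_id", "mature_accession", "read_count"]


def read_isoform_records(paths: Sequence[str | Path] | str | Path) -> pd.DataFrame:
    """Read one or more 3-column isoform TSVs (sample, accession, count)."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = [
        pd.read_csv(p, sep="\t", header=0, names=ISOFORM_COLUMNS) for p in paths
    ]
    return pd.concat(frames, ignore_index=True)


def read_release_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column old-accession -> current-accession TSV."""
    df = pd.read_csv(path, sep="\t", header=0, names=["old", "current"])
    return dict(zip(df["old"], df["current"]))


def aggregate_isoforms(
    records: pd.DataFrame,
    release_map: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum isoform read counts per (current accession, sample).

    Every record's accession is first translated through ``release_map``;
    records whose accession has no entry are excluded from the matrix and
    returned in the unmapped report (accession, n_records, total_reads).

    Returns ``(count_matrix, unmapped_report)`` with the matrix indexed by
    current accession, columns = sample ids.
    """
    records = records[ISOFORM_COLUMNS].copy()
    if len(records) == 0:
        return (
            pd.DataFrame(dtype=float),
            pd.DataFrame(columns=["accession", "n_records", "total_reads"]),
        )
    counts = records["read_count"].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative read count")
    mapped_acc = records["mature_accession"].map(release_map)
    unmapped_mask = mapped_acc.isna()
    unmapped = (
        records.loc[unmapped_mask]
        .groupby("mature_accession")["read_count"]
        .agg(n_records="size", total_reads="sum")
        .reset_index()
        .rename(columns={"mature_accession": "accession"})
    )
    kept = records.loc[~unmapped_mask].assign(accession=mapped_acc[~unmapped_mask])
    matrix = (
        kept.pivot_table(
            index="accession",
            columns="sample_id",
            values="read_count",
            aggfunc="sum",
            fill_value=0,
        )
        .sort_index()
        .astype(float)
    )
    # samples seen only in unmapped records still get (all-zero) columns
    all_samples = pd.Index(sorted(records["sample_id"].unique()))
    matrix = matrix.reindex(columns=all_samples, fill_value=0.0)
    matrix.columns.name = None
    matrix.index.name = "accession"
    return matrix, unmapped


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million over the aggregated mature counts of each sample."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return counts.div(totals, axis=1) * 1e6


def log2_with_zero_replacement(
    rpm: pd.DataFrame, per_mirna: bool = False
) -> pd.DataFrame:
    """log2 transform after replacing zeros with the minimum non-null value.

    The replacement minimum is global over the matrix by default;
    ``per_mirna=True`` uses each row's own minimum non-zero value instead.
    """
    if rpm.size == 0:
        raise ValueError("empty matrix")
    values = rpm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values")
    if not (values > 0).any():
        raise ValueError("all values are zero; nothing to anchor replacement")
    out = values.copy()
    if per_mirna:
        for i in range(out.shape[0]):
            row = out[i]
            nz = row[row > 0]
            if nz.size == 0:
                raise ValueError(
                    f"row {rpm.index[i]!r} is all zero; no per-row minimum"
                )
            row[row == 0] = nz.min()
    else:
        out[out == 0] = values[values > 0].min()
    return pd.DataFrame(np.log2(out), index=rpm.index, columns=rpm.columns)


def two_group_validation(
    log2_matrix: pd.DataFrame,
    sample_groups: Mapping[str, str],
    mirna_subset: Sequence[str],
    group_a: str = "tumor",
    group_b: str = "normal",
) -> pd.DataFrame:
    """Wilcoxon + BH validation of a signature subset in two groups.

    BH adjustment is performed over the subset only (m = subset size), the
    way a focused validation of an a-priori signature is corrected.  Returns
    per-miRNA ``p``, ``q`` and ``direction`` (sign of the median difference,
    group_a minus group_b).
    """
    mirna_subset = list(mirna_subset)
    if not mirna_subset:
        raise ValueError("empty miRNA subset")
    missing = [m for m in mirna_subset if m not in log2_matrix.index]
    if missing:
        raise ValueError(f"subset accession(s) missing from matrix: {missing}")
    sa = [s for s in log2_matrix.columns if sample_groups[s] == group_a]
    sb = [s for s in log2_matrix.columns if sample_groups[s] == group_b]
    if not sa or not sb:
        raise ValueError("both groups must be present")
    a = log2_matrix.loc[mirna_subset, sa].to_numpy()
    b = log2_matrix.loc[mirna_subset, sb].to_numpy()
    pvals = np.array([rank_sum_test(a[i], b[i]) for i in range(len(mirna_subset))])
    med_diff = np.median(a, axis=1) - np.median(b, axis=1)
    return pd.DataFrame(
        {
            "p": pvals,
            "q": bh_adjust(pvals),
            "direction": np.where(med_diff > 0, "up", "down"),
            "median_diff": med_diff,
        },
        index=pd.Index(mirna_subset, name="accession"),
    )


def _split_strata(
    values: Mapping[str, float] | pd.Series,
    strata: Mapping[str, str],
) -> dict[str, np.ndarray]:
    values = pd.Series(values)
    unlabelled = set(values.index) - set(strata)
    if unlabelled:
        raise ValueError(f"samples without stratum: {sorted(unlabelled)}")
    groups: dict[str, list[float]] = {}
    for sample, v in values.items():
        groups.setdefault(strata[sample], []).append(v)
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def kruskal_wallis(
    values: Mapping[str, float] | pd.Series,
    strata: Mapping[str, str],
) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p over k strata.

    ``values`` maps sample -> log2 RPM of one miRNA; ``strata`` maps
    sample -> stratum label.  All-identical data give (0, 1).
    """
    groups = _split_strata(values, strata)
    if len(groups) < 2:
        raise ValueError("need at least 2 strata")
    empty = [k for k, v in groups.items() if v.size == 0]
    if empty:
        raise ValueError(f"empty stratum: {empty}")
    pooled = np.concatenate(list(groups.values()))
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    res = stats.kruskal(*groups.values())
    return float(res.statistic), float(res.pvalue)


def pairwise_strata_tests(
    values: Mapping[str, float] | pd.Series,
    strata: Mapping[str, str],
    reference_stratum: str,
) -> pd.DataFrame:
    """Unadjusted pairwise Wilcoxon p-values across strata.

    Tests every stratum against the reference (e.g. normal thyroid) and
    every pair of non-reference strata against each other.  The p-values
    are reported unadjusted; the global Kruskal–Wallis p gates their
    interpretation.
    """
    groups = _split_strata(values, strata)
    if reference_stratum not in groups:
        raise ValueError(f"reference stratum {reference_stratum!r} absent")
    others = sorted(k for k in groups if k != reference_stratum)
    pairs = [(reference_stratum, o) for o in others]
    pairs += [(a, b) for i, a in enumerate(others) for b in others[i + 1:]]
    rows = [
        {
            "stratum_a": a,
            "stratum_b": b,
            "n_a": groups[a].size,
            "n_b": groups[b].size,
            "p": rank_sum_test(groups[a], groups[b]),
        }
        for a, b in pairs
    ]
    return pd.DataFrame(rows, columns=["stratum_a", "stratum_b", "n_a", "n_b", "p"])
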
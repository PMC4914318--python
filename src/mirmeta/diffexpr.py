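"""Differential-expression signature derivation.

Implements the discovery-stage rules used for the tumor-vs-normal
comparison: a detection filter (a miRNA must be called detected in a
minimum number of samples), a geometric-mean fold change computed on the
log2 scale, a two-sided Wilcoxon rank-sum test (exact by enumeration for
small tie-free groups, normal approximation with tie correction and
continuity correction otherwise), Benjamini–Hochberg FDR control, and the
significance call ``|FC| >= fc_cut AND FDR < fdr_cut``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signature import DOWN, UP, Signature

TUMOR = "tumor"
NORMAL = "normal"

#: Largest per-group size for which the exact rank-sum null is enumerated.
DEFAULT_EXACT_MAX_N = 8

DE_COLUMNS = ["log2fc", "linear_fc", "p", "fdr", "passes"]


@dataclass
class ExpressionMatrix:
    """A miRNA x sample table of log2 expression values.

    ``values`` rows are mature accessions, columns sample ids.  ``detected``
    is an optional boolean table of the same shape (platform detection
    calls).  ``sample_groups`` maps every sample to its group label
    (``tumor`` / ``normal``, or an arbitrary stratum).
    """

    values: pd.DataFrame
    sample_groups: Mapping[str, str]
    detected: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate row or column ids in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")
        missing = set(self.values.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        if self.detected is not None:
            if not self.detected.index.equals(self.values.index) or not (
                self.detected.columns.equals(self.values.columns)
            ):
                raise ValueError("detection table shape mismatch")
            self.detected = self.detected.astype(bool)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == label]

    def to_tsv(self, matrix_path, detected_path=None, groups_path=None) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        if detected_path is not None:
            if self.detected is None:
                raise ValueError("no detection flags to write")
            self.detected.astype(int).to_csv(detected_path, sep="\t")
        if groups_path is not None:
            pd.Series(dict(self.sample_groups), name="group").loc[
                self.values.columns
            ].rename_axis("sample").to_csv(groups_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, matrix_path, groups_path, detected_path=None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"].to_dict()
        detected = None
        if detected_path is not None:
            detected = pd.read_csv(detected_path, sep="\t", index_col=0).astype(bool)
        return cls(values=values, sample_groups=groups, detected=detected)


def detection_filter(matrix: ExpressionMatrix, min_samples: int) -> ExpressionMatrix:
    """Keep the miRNAs detected in at least ``min_samples`` samples."""
    if matrix.detected is None:
        raise ValueError("no detection flags")
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    n_samples = matrix.values.shape[1]
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {n_samples}"
        )
    keep = matrix.detected.sum(axis=1) >= min_samples
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        sample_groups=matrix.sample_groups,
        detected=matrix.detected.loc[keep],
    )


def _signed_linear_fc(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: |FC| = 2^|log2FC|, sign follows log2FC.

    A log2FC of 0 maps to +1 (no change)."""
    return np.where(log2fc >= 0, 2.0 ** log2fc, -(2.0 ** (-log2fc)))


def log2_fold_change(
    matrix: ExpressionMatrix,
    group_a: str = TUMOR,
    group_b: str = NORMAL,
) -> pd.DataFrame:
    """Per-miRNA log2 fold change, ``mean(group_a) - mean(group_b)``.

    Means are taken on the log2 scale, so the linear fold change is a ratio
    of geometric means.  Returns columns ``log2fc`` and ``linear_fc``.
    """
    sa = matrix.group_samples(group_a)
    sb = matrix.group_samples(group_b)
    if not sa or not sb:
        empty = group_a if not sa else group_b
        raise ValueError(f"group {empty!r} has no samples")
    log2fc = matrix.values[sa].mean(axis=1) - matrix.values[sb].mean(axis=1)
    return pd.DataFrame(
        {"log2fc": log2fc, "linear_fc": _signed_linear_fc(log2fc.to_numpy())}
    )


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact p by full enumeration of the rank-sum null when both groups have
    at most ``exact_max_n`` observations and the pooled data are tie-free;
    otherwise the normal approximation with tie-corrected variance and 0.5
    continuity correction.  Degenerate data (all pooled values identical)
    return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    ).pvalue
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str = TUMOR,
    group_b: str = NORMAL,
    method: str = "wilcoxon",
    fc_cut: float = 1.5,
    fdr_cut: float = 0.05,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> pd.DataFrame:
    """Full per-miRNA differential-expression table (a "DE result").

    Columns: ``log2fc``, ``linear_fc``, ``p``, ``fdr`` (BH-adjusted over all
    tested miRNAs) and ``passes`` (the significance call at the supplied
    cuts).  ``method`` is ``"wilcoxon"`` (default) or ``"welch"`` (unequal
    variance t-test).
    """
    fc = log2_fold_change(matrix, group_a, group_b)
    sa = matrix.group_samples(group_a)
    sb = matrix.group_samples(group_b)
    a = matrix.values[sa].to_numpy()
    b = matrix.values[sb].to_numpy()
    if method == "wilcoxon":
        pvals = np.array(
            [rank_sum_test(a[i], b[i], exact_max_n) for i in range(a.shape[0])]
        )
    elif method == "welch":
        pvals = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    de = fc.copy()
    de["p"] = pvals
    de["fdr"] = bh_adjust(pvals)
    de["passes"] = (de["linear_fc"].abs() >= fc_cut) & (de["fdr"] < fdr_cut)
    return de


def call_signature(
    de: pd.DataFrame,
    fc_cut: float = 1.5,
    fdr_cut: float | None = 0.05,
    registry=None,
) -> Signature:
    """Significance call: ``|linear FC| >= fc_cut`` and (if ``fdr_cut`` is
    given) ``FDR < fdr_cut`` strictly.

    Entries are sorted by \\|log2FC\\| descending, ties broken by accession.
    ``registry`` (optional) supplies current names for the output table.
    """
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    if len(de) == 0:
        return Signature()
    keep = de["linear_fc"].abs() >= fc_cut
    if fdr_cut is not None:
        keep &= de["fdr"] < fdr_cut
    hits = de.loc[keep].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, UP, DOWN)
    order = hits.loc[
        sorted(hits.index, key=lambda a: (-abs(hits.at[a, "log2fc"]), a))
    ]
    if registry is not None:
        order["name"] = [registry.current_name(a) for a in order.index]
    cols = [c for c in ["name", "direction", "linear_fc", "log2fc", "p", "fdr"]
            if c in order.columns]
    return Signature(order[cols])
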
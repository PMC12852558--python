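"""TPM normalisation and control-relative transcriptional activity.

TPM (transcripts per million) is the length-normalised relative
abundance

    TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6

so every library's column sums to one million. Viral activity is read
against stably expressed endogenous control genes (e.g. ACT7, H1,
COX2): the per-library ratio of a feature's TPM to the mean control
TPM, presence calls at a TPM floor, between-group fold changes of
arithmetic mean TPM, and the log10 Pearson-clustered matrix behind the
abundance heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from virome_triage.io_formats import LibraryMetadata, QuantRow

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GroupContrast",
    "tpm_from_counts",
    "relative_to_controls",
    "detect_presence",
    "prevalence",
    "group_fold_change",
    "heatmap_matrix",
]


def tpm_from_counts(counts, lengths) -> np.ndarray:
    """Plain TPM from read counts and feature lengths (nt)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(lengths <= 0):
        raise ValueError("all lengths must be > 0")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM is undefined")
    return rate / total * 1e6


@dataclass
class ExpressionMatrix:
    """Features-by-libraries TPM values with library metadata.

    ``values`` is a DataFrame indexed by feature id with one column per
    library; ``control_ids`` names the endogenous control genes used by
    control-relative operations.
    """

    values: pd.DataFrame
    metadata: dict[str, LibraryMetadata] = field(default_factory=dict)
    control_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.control_ids) - set(self.values.index)
        if missing:
            raise ValueError(f"control ids absent from matrix: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_quant_tables(
        cls,
        tables: dict[str, list[QuantRow]],
        metadata: dict[str, LibraryMetadata] | None = None,
        control_ids=(),
        recompute_tpm: bool = True,
    ) -> "ExpressionMatrix":
        """Assemble a TPM matrix from per-library quantification tables.

        With ``recompute_tpm`` (default) TPM is recomputed from counts
        and lengths so columns are guaranteed to sum to one million
        over the loaded feature set; otherwise the tables' own TPM
        column is used as-is.
        """
        columns = {}
        for lib, rows in tables.items():
            names = [r.name for r in rows]
            if recompute_tpm:
                values = tpm_from_counts(
                    [r.num_reads for r in rows], [r.length for r in rows]
                )
            else:
                if any(r.tpm is None for r in rows):
                    raise ValueError(
                        f"library {lib!r} lacks a TPM column; "
                        "use recompute_tpm=True"
                    )
                values = np.array([r.tpm for r in rows], dtype=float)
            columns[lib] = pd.Series(values, index=names)
        df = pd.DataFrame(columns)
        if df.isna().any().any():
            raise ValueError("feature sets differ between libraries")
        return cls(
            values=df,
            metadata=metadata or {},
            control_ids=frozenset(control_ids),
        )


@dataclass
class GroupContrast:
    """A two-group comparison over libraries (e.g. inoculated vs not)."""

    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        self.group_a = frozenset(self.group_a)
        self.group_b = frozenset(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError("groups must be disjoint")


def relative_to_controls(matrix: ExpressionMatrix, feature: str) -> pd.Series:
    """Per-library ratio of a feature's TPM to the mean control TPM.

    Libraries whose mean control TPM is zero get NaN (missing).
    """
    if not matrix.control_ids:
        raise ValueError("matrix has no control genes configured")
    if feature not in matrix.values.index:
        raise KeyError(f"feature {feature!r} absent from matrix")
    control_mean = matrix.values.loc[sorted(matrix.control_ids)].mean(axis=0)
    ratio = matrix.values.loc[feature] / control_mean.where(control_mean > 0)
    return ratio


def detect_presence(matrix: ExpressionMatrix, tpm_threshold: float = 1.0) -> pd.DataFrame:
    """Boolean presence calls: TPM >= threshold.

    At threshold 0 every entry is present (0 >= 0), so a strictly
    positive floor is needed to call absences.
    """
    if tpm_threshold < 0:
        raise ValueError("tpm_threshold must be >= 0")
    return matrix.values >= tpm_threshold


def prevalence(matrix: ExpressionMatrix, tpm_threshold: float = 1.0) -> pd.Series:
    """Number of libraries in which each feature is present."""
    return detect_presence(matrix, tpm_threshold).sum(axis=1)


def group_fold_change(
    matrix: ExpressionMatrix, contrast: GroupContrast, pseudocount: float = 0.0
) -> pd.Series:
    """Per-feature fold change of arithmetic mean TPM between groups.

    fold = (mean_a + pseudocount) / (mean_b + pseudocount); NaN where
    the denominator is zero. Means are of TPM, not of log TPM, so the
    statistic is a ratio of average abundances.
    """
    for group in (contrast.group_a, contrast.group_b):
        missing = group - set(matrix.values.columns)
        if missing:
            raise KeyError(f"libraries absent from matrix: {sorted(missing)}")
    mean_a = matrix.values[sorted(contrast.group_a)].mean(axis=1) + pseudocount
    mean_b = matrix.values[sorted(contrast.group_b)].mean(axis=1) + pseudocount
    return mean_a / mean_b.where(mean_b > 0)


def _correlation_distance(rows: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; zero-variance rows sit at distance 1."""
    n = rows.shape[0]
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    sd = rows.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        logger.info(
            "%d zero-variance row(s) assigned distance 1 to all others",
            degenerate.size,
        )
    ok = np.flatnonzero(sd > 0)
    if ok.size >= 2:
        r = np.corrcoef(rows[ok])
        dist[np.ix_(ok, ok)] = 1.0 - r
        dist[ok, ok] = 0.0
    return np.clip(dist, 0.0, None)


def heatmap_matrix(
    matrix: ExpressionMatrix, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray | None, list[str]]:
    """log10-transformed matrix with Pearson-clustered row order.

    Rows are log10(TPM + pseudocount); row distance is 1 - Pearson r,
    agglomerated with average linkage. Returns (transformed matrix in
    clustered row order, linkage matrix, leaf order). A single-row
    matrix yields a trivial order with no linkage.
    """
    if matrix.values.empty:
        raise ValueError("expression matrix is empty")
    transformed = np.log10(matrix.values + pseudocount)
    if transformed.shape[0] == 1:
        return transformed, None, list(transformed.index)
    dist = _correlation_distance(transformed.to_numpy())
    # enforce exact symmetry before condensing
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="average")
    order = leaves_list(link)
    leaf_ids = [transformed.index[i] for i in order]
    return transformed.iloc[order], link, leaf_ids
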
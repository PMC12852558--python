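"""Compositional virus-to-host assignment.

A virus replicating in a host tends to share the host's genome
signature — codon preferences and dinucleotide odds ratios — so the
rank correlation between a viral compositional profile and candidate
host profiles carries a (weak but cheap) host signal. This module
computes Spearman correlation matrices between viral and host profile
tables, assigns each virus to its best-correlated host, and builds the
average-linkage dendrogram of pooled viruses + hosts on the distance
1 - rho.

Anticorrelation counts as dissimilarity (distance up to 2); the
absolute value is deliberately not taken, since a virus compositionally
opposite to a genome is not adapted to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "CorrelationMatrix",
    "HostAssignment",
    "spearman_matrix",
    "predict_host",
    "hier_cluster",
    "linkage_to_newick",
]


@dataclass
class CorrelationMatrix:
    """Spearman coefficients between row entities and column entities."""

    rho: pd.DataFrame
    n_features: int

    @property
    def row_ids(self) -> list[str]:
        return list(self.rho.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.rho.columns)


@dataclass
class HostAssignment:
    """Best-correlate host call for one virus."""

    virus_id: str
    ranked_hosts: list[tuple[str, float]]
    best_host: str
    margin: float
    tie: bool = False


def _rank_rows(table: pd.DataFrame) -> np.ndarray:
    return np.vstack([rankdata(row, method="average") for row in table.to_numpy()])


def spearman_matrix(
    viral: pd.DataFrame, hosts: pd.DataFrame
) -> CorrelationMatrix:
    """Spearman rho between every viral row and every host row.

    Features are restricted to columns present in both tables (at
    least 2 required); ranks use average ties and rho is Pearson on
    the ranks. A constant profile yields NaN against everything.
    """
    shared = [c for c in viral.columns if c in set(hosts.columns)]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared feature column(s); need at least 2"
        )
    v = _rank_rows(viral[shared])
    h = _rank_rows(hosts[shared])
    v_c = v - v.mean(axis=1, keepdims=True)
    h_c = h - h.mean(axis=1, keepdims=True)
    v_sd = np.sqrt((v_c**2).sum(axis=1))
    h_sd = np.sqrt((h_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (v_c @ h_c.T) / np.outer(v_sd, h_sd)
    rho = np.clip(rho, -1.0, 1.0)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=viral.index, columns=hosts.index),
        n_features=len(shared),
    )


def predict_host(corr: CorrelationMatrix, virus_id: str) -> HostAssignment:
    """Assign a virus to its best-correlated host.

    Hosts are ranked by rho descending with ties broken by host id
    ascending; an exact tie at the top is flagged. All-NaN rows are an
    error.
    """
    if virus_id not in corr.rho.index:
        raise KeyError(f"virus {virus_id!r} absent from correlation matrix")
    row = corr.rho.loc[virus_id].dropna()
    if row.empty:
        raise ValueError(f"all correlations missing for {virus_id!r}")
    ranked = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    best_host, best_rho = ranked[0]
    margin = best_rho - ranked[1][1] if len(ranked) > 1 else 0.0
    tie = len(ranked) > 1 and ranked[1][1] == best_rho
    return HostAssignment(
        virus_id=virus_id,
        ranked_hosts=ranked,
        best_host=best_host,
        margin=margin,
        tie=tie,
    )


def hier_cluster(
    profiles: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of pooled entities on 1 - Spearman rho.

    ``profiles`` is an entities-by-features table (viruses and hosts
    pooled). Returns (linkage matrix, deterministic leaf order).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 entities to cluster")
    corr = spearman_matrix(profiles, profiles)
    dist = 1.0 - corr.rho.to_numpy()
    dist = np.nan_to_num(dist, nan=1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="average")
    order = leaves_list(link)
    return link, [profiles.index[i] for i in order]


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialise a linkage matrix as a newick string with branch lengths."""
    tree = to_tree(link)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
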
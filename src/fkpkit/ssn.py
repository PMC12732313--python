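"""Sequence similarity networks from all-by-all pairwise identity.

Proteins are nodes; an undirected edge joins two proteins whose global
pairwise percent identity meets a threshold (the in-repo analogue of an
EFI-EST all-by-all comparison keyed on identity rather than alignment
score).  Connected components above a minimum size are the SSN clusters,
and their congruence with phylogenetic clades is summarized as a
contingency table with per-cluster purity.
"""

from __future__ import annotations

from typing import Literal, Optional

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "make_aligner",
    "pairwise_identity",
    "identity_matrix",
    "build_ssn",
    "ssn_clusters",
    "cluster_clade_congruence",
]


def make_aligner(
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    match_matrix: Optional[str] = "BLOSUM62",
    match_score: float = 1.0,
    mismatch_score: float = -1.0,
) -> Align.PairwiseAligner:
    """Global affine-gap aligner; BLOSUM62 by default, or simple match/mismatch."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if match_matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(match_matrix)
    else:
        aligner.match_score = match_score
        aligner.mismatch_score = mismatch_score
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    aligner: Optional[Align.PairwiseAligner] = None,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> float:
    """Percent identity of the best global alignment of two sequences.

    Identity is 100 * matches / alignment length (gap columns included);
    ``denominator="shorter"`` divides by the shorter sequence length
    instead.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    denom = len(ga) if denominator == "alignment" else min(len(a), len(b))
    return 100.0 * matches / denom


def identity_matrix(
    proteins: dict[str, str],
    aligner: Optional[Align.PairwiseAligner] = None,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> pd.DataFrame:
    """Symmetric all-by-all percent-identity matrix (diagonal 100)."""
    if aligner is None:
        aligner = make_aligner()
    ids = list(proteins)
    mat = np.full((len(ids), len(ids)), 100.0)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pid = pairwise_identity(
                proteins[ids[i]], proteins[ids[j]], aligner, denominator
            )
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=ids, columns=ids)


def build_ssn(scores: pd.DataFrame, identity_threshold: float) -> nx.Graph:
    """Graph with an edge wherever pairwise identity >= threshold."""
    if not 0.0 <= identity_threshold <= 100.0:
        raise ValueError("identity threshold must be within [0, 100]")
    if list(scores.index) != list(scores.columns):
        raise ValueError("score matrix must be square with matching labels")
    g = nx.Graph()
    ids = list(scores.index)
    g.add_nodes_from(ids)
    vals = scores.to_numpy()
    if not np.allclose(vals, vals.T):
        raise ValueError("score matrix must be symmetric")
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] >= identity_threshold:
                g.add_edge(ids[i], ids[j], identity=float(vals[i, j]))
    return g


UNCLUSTERED = 0


def ssn_clusters(graph: nx.Graph, min_size: int = 2) -> dict[str, int]:
    """Number connected components by decreasing size, then smallest member.

    Components below ``min_size`` get the label 0 ("unclustered").
    """
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    assignment: dict[str, int] = {}
    k = 1
    for comp in comps:
        if len(comp) >= min_size:
            label, k = k, k + 1
        else:
            label = UNCLUSTERED
        for node in comp:
            assignment[node] = label
    return assignment


def cluster_clade_congruence(
    clusters: dict[str, int],
    clade_map: dict[str, str],
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Cluster x clade contingency table with purity summaries.

    Returns (contingency counts, per-cluster purity, overall weighted
    purity).  Purity of a cluster is the fraction of its members in its
    majority clade.  Unclustered nodes (label 0) are excluded from purity.
    """
    missing = sorted(m for m in clusters if m not in clade_map)
    if missing:
        raise KeyError(f"members missing clade labels: {missing[:10]}")
    df = pd.DataFrame(
        {
            "cluster": pd.Series(clusters),
            "clade": pd.Series({m: clade_map[m] for m in clusters}),
        }
    )
    table = pd.crosstab(df["cluster"], df["clade"])
    clustered = table.loc[table.index != UNCLUSTERED]
    if clustered.empty:
        return table, pd.Series(dtype=float), float("nan")
    purity = clustered.max(axis=1) / clustered.sum(axis=1)
    overall = float(
        (purity * clustered.sum(axis=1)).sum() / clustered.to_numpy().sum()
    )
    return table, purity, overall
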
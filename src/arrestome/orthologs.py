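"""Cross-species interactome comparison via ortholog groups.

Ortholog predictions (DIOPT-style confidence scores with a prediction
direction) are filtered, high-confidence preys of the two species are
grouped into connected components of the retained pairs, and the bait x
ortholog-group matrix of log2 mean spectral counts is hierarchically
clustered with correlation distance and Ward linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .data_model import FormatError, SpectralCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologGroup",
    "ClusterResult",
    "filter_orthologs",
    "build_ortholog_groups",
    "build_matrix",
    "cluster",
    "linkage_to_newick",
]

_DIRECTIONS = ("forward", "reverse")


@dataclass(frozen=True)
class OrthologGroup:
    """A connected component of retained cross-species ortholog pairs."""

    group_id: str
    members_a: frozenset[str]
    members_b: frozenset[str]
    pairs: tuple[tuple[str, str, float], ...]  # (protein_a, protein_b, score)

    @property
    def members(self) -> frozenset[str]:
        return self.members_a | self.members_b


def filter_orthologs(
    pairs: pd.DataFrame,
    min_score: float = 2,
    require_reciprocal: bool = True,
) -> pd.DataFrame:
    """Filter ortholog predictions by confidence and reciprocity.

    ``pairs`` has columns (protein_a, protein_b, score, direction) where
    direction is "forward" (A predicted to map to B) or "reverse".  Pairs
    with score >= ``min_score`` are kept; with ``require_reciprocal`` a
    pair must additionally be predicted in both directions (each passing
    the score threshold).  The result has one row per retained unordered
    pair with the maximum supporting score.
    """
    required = ("protein_a", "protein_b", "score", "direction")
    missing = [c for c in required if c not in pairs.columns]
    if missing:
        raise FormatError(f"ortholog table missing column(s) {missing}")
    bad = ~pairs["direction"].isin(_DIRECTIONS)
    if bad.any():
        raise FormatError(
            f"malformed direction flag(s) {sorted(pairs.loc[bad, 'direction'].unique())}; "
            f"expected one of {_DIRECTIONS}"
        )
    kept = pairs[pairs["score"] >= min_score]
    grouped = kept.groupby(["protein_a", "protein_b"]).agg(
        score=("score", "max"), directions=("direction", lambda s: frozenset(s))
    )
    if require_reciprocal:
        grouped = grouped[grouped["directions"].map(len) == 2]
    out = grouped.reset_index()[["protein_a", "protein_b", "score"]]
    return out.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)


def build_ortholog_groups(
    retained: pd.DataFrame,
    preys_a: set[str],
    preys_b: set[str],
) -> list[OrthologGroup]:
    """Ortholog prey groups: connected components of the retained-pair
    graph restricted to the high-confidence preys of the two species.
    Groups partition the preys that carry at least one retained pair."""
    g = nx.Graph()
    for row in retained.itertuples(index=False):
        if row.protein_a in preys_a and row.protein_b in preys_b:
            g.add_edge(row.protein_a, row.protein_b, score=float(row.score))
    groups = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components, start=1):
        sub = g.subgraph(comp)
        pairs = tuple(
            sorted((a, b, d["score"]) if a in preys_a else (b, a, d["score"])
                   for a, b, d in sub.edges(data=True))
        )
        groups.append(
            OrthologGroup(
                group_id=f"OG{i:03d}",
                members_a=frozenset(comp & preys_a),
                members_b=frozenset(comp & preys_b),
                pairs=pairs,
            )
        )
    return groups


def build_matrix(
    groups: Sequence[OrthologGroup],
    counts_a: SpectralCountTable,
    counts_b: SpectralCountTable,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Ortholog-group x bait matrix of log2 mean spectral counts.

    For each bait, counts of the group's same-species members are summed
    per replicate, averaged over replicates and log2-transformed with a
    pseudocount: entry = log2(pseudocount + mean_r sum_members count).
    Baits of both species form the columns; undetected groups yield
    log2(pseudocount).
    """
    if not groups:
        raise ValueError("no ortholog groups to tabulate")
    cols: dict[str, np.ndarray] = {}
    for table, side in ((counts_a, "a"), (counts_b, "b")):
        for bait in table.baits():
            mat = table.matrix(bait)  # prey x replicate
            vals = np.empty(len(groups))
            for gi, grp in enumerate(groups):
                members = sorted(grp.members_a if side == "a" else grp.members_b)
                present = [m for m in members if m in mat.index]
                total_per_rep = (
                    mat.loc[present].sum(axis=0).to_numpy()
                    if present
                    else np.zeros(table.n_replicates)
                )
                vals[gi] = np.log2(pseudocount + total_per_rep.mean())
            cols[bait] = vals
    return pd.DataFrame(cols, index=[g.group_id for g in groups])


@dataclass
class ClusterResult:
    """Dendrogram and flat clusters along one axis of the matrix."""

    labels: list[str]
    linkage: np.ndarray
    flat: dict[str, int]
    newick: str


def _correlation_distance(mat: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows; zero-variance rows get
    correlation 0 (distance 1) with a warning rather than NaN."""
    n = mat.shape[0]
    sd = mat.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance vector(s); their correlation is taken as 0",
                       int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    return dist[np.triu_indices(n, k=1)]


def cluster(
    matrix: pd.DataFrame,
    axis: str = "columns",
    n_clusters: int | None = None,
) -> ClusterResult:
    """Hierarchical clustering of matrix rows or columns.

    Distance is 1 - Pearson correlation, linkage is Ward's method, and an
    optional flat cut at ``n_clusters`` labels the leaves.  Needs at least
    two items on the clustered axis.
    """
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index) if axis == "rows" else list(matrix.columns)
    if axis == "columns":
        data = data.T
    if len(labels) < 2:
        raise ValueError(f"need >= 2 items on the {axis} axis, got {len(labels)}")
    condensed = _correlation_distance(data)
    link = hierarchy.ward(condensed)
    flat: dict[str, int] = {}
    if n_clusters is not None:
        assignments = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
        flat = {lab: int(c) for lab, c in zip(labels, assignments)}
    return ClusterResult(labels, link, flat, linkage_to_newick(link, labels))


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def groups_frame(groups: Sequence[OrthologGroup]) -> pd.DataFrame:
    rows = [
        {
            "group_id": g.group_id,
            "members_a": ";".join(sorted(g.members_a)),
            "members_b": ";".join(sorted(g.members_b)),
            "n_pairs": len(g.pairs),
        }
        for g in groups
    ]
    return pd.DataFrame(rows, columns=["group_id", "members_a", "members_b", "n_pairs"])
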
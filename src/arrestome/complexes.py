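"""Protein-complex association scoring against a bait's interactome.

A known protein complex is associated with a bait when its subunits carry
high interaction-probability scores in that bait's AP/MS data.  The
association statistic is the interquartile mean (IQM) of the subunit
scores

    IQM = sum_{i=Q1..Q3} score_(i) / (Q3 - Q1 + 1)

over the ascending-sorted scores, with first/third quartile ranks
Q1 = floor(N/4) + 1 and Q3 = floor(3N/4) for a complex of N subunits.
Trimming both tails makes the statistic robust to one or two spuriously
high subunits while still penalising complexes whose members are largely
undetected (absent subunits score 0 and count toward N).

Significance is assessed against a null of random same-size complexes
drawn from the input-protein universe; redundant complexes from different
source databases are merged greedily by overlap coefficient
|X n Y| / min(|X|, |Y|) and pruned before the final permutation pass with
Benjamini-Hochberg correction per bait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import ComplexDatabase, HighConfidenceNetwork, ProteinComplex

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexScore",
    "MergedComplex",
    "overlap_coefficient",
    "quartile_ranks",
    "iqm",
    "iqm_score",
    "permutation_pvalue",
    "merge_complexes",
    "prune_complexes",
    "complex_enrichment_pipeline",
]


@dataclass
class ComplexScore:
    """IQM association score of one (bait, complex) pair with its
    permutation significance."""

    complex_id: str
    bait: str
    n_subunits: int
    q1: int
    q3: int
    iqm: float
    p: float = np.nan
    q: float = np.nan
    n_perm: int = 0


@dataclass
class MergedComplex:
    """Union of source complexes agglomerated by overlap coefficient."""

    merged_id: str
    members: tuple[str, ...]  # source complex ids
    subunits: frozenset[str]
    edges: frozenset[tuple[str, str]] = frozenset()
    provenance: tuple[tuple[str, str, float], ...] = ()  # (id_a, id_b, coefficient) per merge

    @property
    def size(self) -> int:
        return len(self.subunits)


def overlap_coefficient(x: Iterable[str], y: Iterable[str]) -> float:
    """Overlap (Szymkiewicz-Simpson) coefficient |X n Y| / min(|X|, |Y|)."""
    xs, ys = set(x), set(y)
    if not xs or not ys:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(xs & ys) / min(len(xs), len(ys))


def quartile_ranks(n: int) -> tuple[int, int]:
    """1-based quartile ranks (Q1, Q3) for a complex of n subunits:
    Q1 = floor(n/4) + 1, Q3 = floor(3n/4), clamped so Q3 >= Q1."""
    q1 = n // 4 + 1
    q3 = max((3 * n) // 4, q1)
    return q1, q3


def iqm(scores: np.ndarray) -> float:
    """Interquartile mean of a 1-D score array (any order)."""
    s = np.sort(np.asarray(scores, dtype=float))
    q1, q3 = quartile_ranks(s.size)
    return float(s[q1 - 1 : q3].mean())


def iqm_score(
    subunits: Iterable[str], score_of: Mapping[str, float], complex_id: str = "", bait: str = ""
) -> ComplexScore:
    """IQM complex-association score for one bait.

    ``score_of`` maps detected preys to that bait's interaction scores;
    subunits absent from the map score 0, so undetected members drag the
    statistic down.  Complexes with fewer than 3 subunits are rejected
    (they are pruned from the analysis anyway).
    """
    members = sorted(set(subunits))
    n = len(members)
    if n < 3:
        raise ValueError(f"complex {complex_id or '?'} has {n} subunits; need >= 3")
    scores = np.array([float(score_of.get(m, 0.0)) for m in members])
    q1, q3 = quartile_ranks(n)
    return ComplexScore(
        complex_id=complex_id, bait=bait, n_subunits=n, q1=q1, q3=q3, iqm=iqm(scores)
    )


def null_iqm_distribution(
    universe_scores: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """IQMs of ``n_perm`` random complexes of ``size`` proteins drawn
    uniformly without replacement from the universe (vectorised)."""
    u = universe_scores.size
    if u < size:
        raise ValueError(f"universe ({u}) smaller than complex ({size})")
    # random subsets via argsort of uniform keys, one row per permutation
    idx = np.argsort(rng.random((n_perm, u)), axis=1)[:, :size]
    draws = np.sort(universe_scores[idx], axis=1)
    q1, q3 = quartile_ranks(size)
    return draws[:, q1 - 1 : q3].mean(axis=1)


def permutation_pvalue(
    subunits: Iterable[str],
    universe: Iterable[str],
    score_of: Mapping[str, float],
    n_perm: int = 1000,
    seed: int = 0,
    null: np.ndarray | None = None,
) -> tuple[float, float]:
    """Permutation p-value of a complex's IQM score for one bait.

    The null distribution is the IQM of random same-size complexes drawn
    from ``universe``; the add-one estimator
    p = (1 + #{null >= observed}) / (n_perm + 1) never returns exactly 0.
    A precomputed ``null`` array (shared across same-size complexes) may
    be passed to amortise the sampling.  Returns (p, observed IQM).
    """
    members = sorted(set(subunits))
    observed = iqm(np.array([float(score_of.get(m, 0.0)) for m in members]))
    if null is None:
        universe_list = sorted(set(universe))
        scores = np.array([float(score_of.get(p, 0.0)) for p in universe_list])
        rng = np.random.default_rng(seed)
        null = null_iqm_distribution(scores, len(members), n_perm, rng)
    p = (1.0 + np.sum(null >= observed)) / (null.size + 1.0)
    return float(p), observed


# ---------------------------------------------------------------------------
# Merging and pruning
# ---------------------------------------------------------------------------


def _as_merged(c: ProteinComplex) -> MergedComplex:
    return MergedComplex(
        merged_id=c.complex_id, members=(c.complex_id,), subunits=c.subunits, edges=c.edges
    )


def merge_complexes(
    db: ComplexDatabase | Sequence[MergedComplex], threshold: float = 0.5
) -> list[MergedComplex]:
    """Greedy agglomeration of redundant complexes by overlap coefficient.

    Repeatedly the pair of complexes with the highest overlap coefficient
    is replaced by their union (subunits and edges unioned, provenance
    appended) while that maximum exceeds ``threshold``; ties are broken on
    the lexicographically smallest (id_a, id_b) pair, which makes the
    result independent of input ordering.  Unmerged complexes pass through
    untouched.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"merge threshold must be in (0, 1], got {threshold}")
    if isinstance(db, ComplexDatabase):
        current = {c.complex_id: _as_merged(c) for c in db}
    else:
        current = {c.merged_id: c for c in db}
    while len(current) > 1:
        best: tuple[float, str, str] | None = None
        ids = sorted(current)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                coef = overlap_coefficient(current[a].subunits, current[b].subunits)
                if best is None or coef > best[0] or (coef == best[0] and (a, b) < best[1:]):
                    best = (coef, a, b)
        assert best is not None
        coef, a, b = best
        if coef <= threshold:
            break
        ca, cb = current.pop(a), current.pop(b)
        merged = MergedComplex(
            merged_id=f"{a}+{b}",
            members=tuple(sorted(ca.members + cb.members)),
            subunits=ca.subunits | cb.subunits,
            edges=ca.edges | cb.edges,
            provenance=ca.provenance + cb.provenance + ((a, b, coef),),
        )
        current[merged.merged_id] = merged
    return [current[k] for k in sorted(current)]


def prune_complexes(
    merged: Sequence[MergedComplex],
    network: HighConfidenceNetwork,
    min_subunits: int = 3,
    min_ppis: int = 2,
    ppi_rule: str = "bait-subunit",
    missing_edges: str = "keep",
) -> list[MergedComplex]:
    """Prune merged complexes before the final significance pass.

    Applied per complex: (i) subunits with degree 0 in the intra-complex
    edge set are dropped; (ii) complexes with fewer than ``min_subunits``
    remaining subunits are removed; (iii) complexes with fewer than
    ``min_ppis`` PPIs are removed, where the PPI count is, under the
    default ``bait-subunit`` rule, the number of high-confidence bait-prey
    interactions whose prey is a remaining subunit (the ``intra-complex``
    rule counts surviving subunit-subunit edges instead).

    A complex carrying no edge set is handled per ``missing_edges``:
    ``"keep"`` (default) retains all its subunits through step (i) with a
    log message; ``"reject"`` raises.
    """
    if ppi_rule not in ("bait-subunit", "intra-complex"):
        raise ValueError(f"unknown ppi_rule {ppi_rule!r}")
    hc_pairs = network.pairs()
    out: list[MergedComplex] = []
    for c in merged:
        if c.edges:
            g = nx.Graph()
            g.add_nodes_from(c.subunits)
            g.add_edges_from(c.edges)
            connected = frozenset(n for n in c.subunits if g.degree[n] > 0)
        else:
            if missing_edges == "reject":
                raise ValueError(f"complex {c.merged_id} has no intra-complex edge set")
            logger.info(
                "complex %s has no edge set; keeping all %d subunits", c.merged_id, c.size
            )
            connected = c.subunits
        if len(connected) < min_subunits:
            continue
        edges = frozenset(e for e in c.edges if e[0] in connected and e[1] in connected)
        if ppi_rule == "bait-subunit":
            n_ppis = sum(1 for bait, prey in hc_pairs if prey in connected)
        else:
            n_ppis = len(edges)
        if n_ppis < min_ppis:
            continue
        out.append(
            MergedComplex(c.merged_id, c.members, connected, edges, c.provenance)
        )
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _bait_score_maps(network: HighConfidenceNetwork) -> dict[str, dict[str, float]]:
    return {bait: network.score_of(bait) for bait in network.baits()}


def complex_enrichment_pipeline(
    network: HighConfidenceNetwork,
    complex_dbs: Sequence[ComplexDatabase],
    n_perm: int = 1000,
    seed: int = 0,
    screen_p: float = 0.05,
    merge_threshold: float = 0.5,
    fdr_cutoff: float = 0.2,
    universe: Iterable[str] | None = None,
    ppi_rule: str = "bait-subunit",
) -> tuple[list[ComplexScore], list[MergedComplex]]:
    """Four-stage complex association analysis.

    Stage 1 scores every source complex (>= 3 subunits) against every bait
    with the IQM statistic and a permutation test, keeping (bait, complex)
    pairs with p < ``screen_p``.  Stage 2 merges the surviving complexes
    (pooled across source databases) by overlap coefficient.  Stage 3
    prunes disconnected subunits and under-supported complexes.  Stage 4
    rescores the merged complexes, recomputes permutation p-values per
    bait, applies Benjamini-Hochberg correction within bait, and keeps
    associations with q < ``fdr_cutoff``.

    The permutation universe defaults to all proteins appearing in any
    input complex database.  Null distributions are shared across
    same-size complexes of one bait (they are exchangeable), which keeps
    the permutation pass linear in the number of distinct sizes.

    Returns (passing ComplexScores, the pruned merged complexes).
    """
    if not complex_dbs:
        raise ValueError("at least one complex database is required")
    pooled = ComplexDatabase.pooled(complex_dbs)
    if universe is None:
        universe_list = sorted(pooled.proteins())
    else:
        universe_list = sorted(set(universe))
    score_maps = _bait_score_maps(network)
    rng = np.random.default_rng(seed)

    def null_cache(score_map: Mapping[str, float]) -> dict[int, np.ndarray]:
        return {}

    def get_null(cache: dict[int, np.ndarray], scores: np.ndarray, size: int) -> np.ndarray:
        if size not in cache:
            cache[size] = null_iqm_distribution(scores, size, n_perm, rng)
        return cache[size]

    # stage 1: per-bait screen of source complexes
    survivors: set[str] = set()
    for bait in network.baits():
        score_map = score_maps[bait]
        uscores = np.array([float(score_map.get(p, 0.0)) for p in universe_list])
        cache: dict[int, np.ndarray] = null_cache(score_map)
        for c in pooled:
            if c.size < 3:
                continue
            null = get_null(cache, uscores, c.size)
            p, _ = permutation_pvalue(c.subunits, universe_list, score_map, null=null)
            if p < screen_p:
                survivors.add(c.complex_id)
    logger.info("stage 1: %d/%d source complexes pass p < %g for some bait",
                len(survivors), len(pooled), screen_p)

    # stage 2: merge survivors pooled across sources
    surviving_db = ComplexDatabase()
    for cid in sorted(survivors):
        surviving_db.add(pooled.complexes[cid])
    merged = merge_complexes(surviving_db, threshold=merge_threshold)

    # stage 3: prune
    pruned = prune_complexes(merged, network, ppi_rule=ppi_rule)
    logger.info("stage 2/3: %d merged complexes, %d after pruning", len(merged), len(pruned))

    # stage 4: rescore, permutation p, BH within bait
    results: list[ComplexScore] = []
    for bait in network.baits():
        score_map = score_maps[bait]
        uscores = np.array([float(score_map.get(p, 0.0)) for p in universe_list])
        cache = null_cache(score_map)
        bait_scores: list[ComplexScore] = []
        for c in pruned:
            cs = iqm_score(c.subunits, score_map, complex_id=c.merged_id, bait=bait)
            null = get_null(cache, uscores, c.size)
            cs.p = (1.0 + float(np.sum(null >= cs.iqm))) / (null.size + 1.0)
            cs.n_perm = n_perm
            bait_scores.append(cs)
        if bait_scores:
            qvals = multipletests([c.p for c in bait_scores], method="fdr_bh")[1]
            for cs, q in zip(bait_scores, qvals):
                cs.q = float(q)
        results.extend(cs for cs in bait_scores if cs.q < fdr_cutoff)
    logger.info("stage 4: %d (bait, complex) associations at q < %g", len(results), fdr_cutoff)
    return results, pruned


def scores_frame(results: Sequence[ComplexScore], merged: Sequence[MergedComplex]) -> pd.DataFrame:
    """Flatten pipeline results into the output TSV layout."""
    members = {m.merged_id: ";".join(m.members) for m in merged}
    rows = [
        {
            "bait": r.bait,
            "complex_id": r.complex_id,
            "n_subunits": r.n_subunits,
            "iqm": r.iqm,
            "p": r.p,
            "q": r.q,
            "members": members.get(r.complex_id, r.complex_id),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["bait", "complex_id", "n_subunits", "iqm", "p", "q", "members"]
    )
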
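"""Motif-domain affinity support, EASE domain enrichment and localization.

Short-linear motifs on the baits (e.g. PPxY) bind known partner domains on
prey proteins (e.g. WW); a PPI "supported" by such a known affinity is
independent evidence that the interaction is genuine.  This module flags
supported PPIs, tests whether the filtered network is enriched for them,
runs the conservatively decremented Fisher (EASE) domain-enrichment test
per bait, and builds 1/k-weighted subcellular-localization profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    AnnotationBundle,
    EnrichmentResult,
    HighConfidenceNetwork,
    LOCALIZATION_TERMS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SupportAnnotation",
    "annotate_supported",
    "support_enrichment_test",
    "ease_enrichment",
    "fisher_greater",
    "localization_profile",
]


@dataclass
class SupportAnnotation:
    """Per-PPI affinity-support flags for one network.

    ``support`` maps (bait, prey) to the set of (motif, domain) pairs that
    back it; unsupported PPIs map to an empty set.
    """

    support: dict[tuple[str, str], set[tuple[str, str]]]

    @property
    def n_total(self) -> int:
        return len(self.support)

    @property
    def n_supported(self) -> int:
        return sum(1 for pairs in self.support.values() if pairs)

    def supported_pairs(self) -> set[tuple[str, str]]:
        return {ppi for ppi, pairs in self.support.items() if pairs}


def annotate_supported(
    network: HighConfidenceNetwork | Sequence[tuple[str, str]],
    ann: AnnotationBundle,
) -> SupportAnnotation:
    """Flag each PPI supported by a known motif-domain affinity.

    A PPI (bait, prey) is supported when some motif annotated on the bait
    and some domain annotated on the prey form a pair present in the known
    affinity table.  Baits with no motif annotation contribute zero
    support (logged).
    """
    if isinstance(network, HighConfidenceNetwork):
        ppis = sorted(network.pairs())
    else:
        ppis = sorted(set(network))
    warned: set[str] = set()
    support: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for bait, prey in ppis:
        motifs = ann.bait_motifs.get(bait, set())
        if not motifs and bait not in warned:
            logger.warning("bait %s has no motif annotation; its PPIs cannot be supported", bait)
            warned.add(bait)
        domains = ann.prey_domains.get(prey, set())
        support[(bait, prey)] = {
            (m, d) for m in motifs for d in domains if (m, d) in ann.affinities
        }
    return SupportAnnotation(support)


def fisher_greater(table: Sequence[Sequence[int]]) -> float:
    """One-sided (greater) Fisher exact p-value of a 2x2 table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="greater")[1])


def support_enrichment_test(
    high_conf: SupportAnnotation, raw: SupportAnnotation
) -> EnrichmentResult:
    """Test enrichment of affinity-supported PPIs in the filtered network.

    The raw stratum is taken as raw-minus-high-confidence so the two rows
    of the 2x2 table [supported/unsupported x high-confidence/raw-only]
    are disjoint; the p-value is a one-sided (greater) Fisher exact test.
    Reported uncorrected: it is a single test per network pair.
    """
    if high_conf.n_total == 0 or raw.n_total == 0:
        raise ValueError("support enrichment needs non-empty networks in both strata")
    hc_pairs = set(high_conf.support)
    raw_only = {ppi: pairs for ppi, pairs in raw.support.items() if ppi not in hc_pairs}
    a = high_conf.n_supported
    b = high_conf.n_total - a
    c = sum(1 for pairs in raw_only.values() if pairs)
    d = len(raw_only) - c
    p = fisher_greater([[a, b], [c, d]])
    odds = (a * d) / (b * c) if b * c else np.inf
    return EnrichmentResult(
        unit="support_enrichment",
        statistic=float(odds),
        p_value=p,
        q_value=p,
        components={"table": [[a, b], [c, d]]},
    )


@dataclass
class EaseTable:
    """Per-(bait, domain) EASE enrichment results."""

    table: pd.DataFrame  # bait, domain, a, query_size, bg_with, bg_size, p, q

    def significant(self, q_cutoff: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] <= q_cutoff].reset_index(drop=True)


def ease_p(a: int, b: int, c: int, d: int) -> float:
    """EASE score: one-sided Fisher p after decrementing the observed
    query-with-feature cell by one (floored at zero).  The decrement makes
    single-gene overlaps never significant (p = 1 exactly when a <= 1)."""
    return fisher_greater([[max(a - 1, 0), b], [c, d]])


def ease_enrichment(
    network: HighConfidenceNetwork,
    domains: Mapping[str, set[str]],
    background: set[str],
    q_cutoff: float = 0.05,
) -> EaseTable:
    """Domain enrichment per bait with the EASE (decremented Fisher) score.

    For each bait the query is its prey set; for each domain seen in the
    query, the 2x2 table [query-with-domain, query-without;
    background-other-with, background-other-without] is built over the
    supplied background universe, the query-with cell is decremented by
    one, and a one-sided greater Fisher p is computed.  BH correction is
    applied within each bait's family of domains.
    """
    missing = set(network.preys()) - background
    if missing:
        raise ValueError(
            f"background does not cover {len(missing)} network preys, e.g. {sorted(missing)[:3]}"
        )
    bg_with: dict[str, int] = {}
    for prot in background:
        for dom in domains.get(prot, set()):
            bg_with[dom] = bg_with.get(dom, 0) + 1
    n_bg = len(background)
    rows = []
    for bait in network.baits():
        query = network.preys_of(bait)
        n_query = len(query)
        query_domains = sorted({d for p in query for d in domains.get(p, set())})
        pvals = []
        for dom in query_domains:
            if dom not in bg_with:
                raise ValueError(f"domain {dom} absent from the background universe")
            a = sum(1 for p in query if dom in domains.get(p, set()))
            b = n_query - a
            c = bg_with[dom] - a
            d = (n_bg - n_query) - c
            pvals.append(ease_p(a, b, c, d))
            rows.append(
                {
                    "bait": bait,
                    "domain": dom,
                    "a": a,
                    "query_size": n_query,
                    "bg_with": bg_with[dom],
                    "bg_size": n_bg,
                    "p": pvals[-1],
                }
            )
        if pvals:
            qvals = multipletests(pvals, method="fdr_bh")[1]
            for q, row in zip(qvals, rows[-len(pvals):]):
                row["q"] = float(q)
    df = pd.DataFrame(rows, columns=["bait", "domain", "a", "query_size", "bg_with", "bg_size", "p", "q"])
    return EaseTable(df)


def localization_profile(
    preys_per_bait: Mapping[str, set[str]],
    localizations: Mapping[str, set[str]],
    vocabulary: Sequence[str] = LOCALIZATION_TERMS,
) -> pd.DataFrame:
    """Weighted subcellular-localization profile per bait.

    Each annotated prey distributes a unit of weight equally over its k
    annotated terms (1/k each); preys with no annotation within the
    vocabulary are excluded from the denominator.  Rows (baits) sum to 1
    whenever at least one prey is annotated.
    """
    vocab = list(vocabulary)
    vocab_set = set(vocab)
    rows = {}
    for bait, preys in preys_per_bait.items():
        weights = dict.fromkeys(vocab, 0.0)
        n_annotated = 0
        for prey in sorted(preys):
            terms = localizations.get(prey, set()) & vocab_set
            if not terms:
                continue
            n_annotated += 1
            w = 1.0 / len(terms)
            for t in terms:
                weights[t] += w
        if n_annotated:
            rows[bait] = {t: weights[t] / n_annotated for t in vocab}
        else:
            rows[bait] = {t: np.nan for t in vocab}
    return pd.DataFrame.from_dict(rows, orient="index", columns=vocab)
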
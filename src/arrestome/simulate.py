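"""Truth-labelled synthetic AP/MS data generator.

Emulates the statistical structure the analysis assumes: a handful of
baits purified in replicate, a contaminant background shared with
negative-control runs (CRAPome-style), planted true interactions with
elevated spectral counts, planted protein complexes enriched in true
interactors, and planted motif-domain affinity structure.  Counts are
negative-binomial (AP/MS counts are overdispersed relative to Poisson).

The score generator is an explicit stand-in for an external SAINT-style
scoring tool: a logistic function of the bait/control log fold-change
with an empirical-FDR BFDR column.  It preserves the only properties the
downstream pipeline relies on (a monotone probability-like score and a
valid, monotone BFDR), not the tool's internal model.

Every generator is deterministic given the config seed and emits the
exact tabular formats the readers in :mod:`arrestome.data_model` accept.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AnnotationBundle,
    ComplexDatabase,
    LOCALIZATION_TERMS,
    ProteinComplex,
    ScoredInteraction,
    SpectralCountTable,
)

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_apms",
    "simulate_scores",
    "plant_complexes",
    "plant_annotations",
    "simulate_dataset",
    "SimulatedDataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic AP/MS study.

    Counts for true bait-prey interactions follow NB(signal_mean,
    signal_dispersion) in bait runs; contaminant preys follow
    NB(background_mean, background_dispersion) in bait *and* control
    runs; all other pairs are zero.  Scores are
    logistic(score_slope * log2 fold-change - score_offset).
    """

    n_baits: int = 6
    n_preys: int = 300
    replicates: int = 2
    n_control_runs: int = 4
    true_interaction_rate: float = 0.05
    signal_mean: float = 50.0
    signal_dispersion: float = 5.0
    background_mean: float = 2.0
    background_dispersion: float = 2.0
    contaminant_fraction: float = 0.3
    score_slope: float = 2.0
    score_offset: float = 2.0
    n_planted_complexes: int = 5
    n_decoy_complexes: int = 50
    complex_size_min: int = 4
    complex_size_max: int = 8
    planted_purity: float = 0.8
    extra_edge_prob: float = 0.3
    support_rate_true: float = 0.6
    support_rate_false: float = 0.05
    localization_rate: float = 0.8
    ortholog_coverage: float = 1.0
    min_ortholog_score: float = 2.0
    max_ortholog_score: float = 15.0
    bait_prefix: str = "B"
    prey_prefix: str = "P"
    species: str = "simA"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "true_interaction_rate",
            "contaminant_fraction",
            "planted_purity",
            "extra_edge_prob",
            "support_rate_true",
            "support_rate_false",
            "localization_rate",
            "ortholog_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field {name}={v} must be in [0, 1]")
        for name in (
            "signal_mean",
            "signal_dispersion",
            "background_mean",
            "background_dispersion",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"config field {name}={v} must be positive")
        for name in ("n_baits", "n_preys", "replicates", "n_control_runs"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"config field {name}={v} must be >= 1")
        if self.complex_size_min < 3 or self.complex_size_max < self.complex_size_min:
            raise ValueError(
                f"config fields complex_size_min/max=({self.complex_size_min}, "
                f"{self.complex_size_max}) must satisfy 3 <= min <= max"
            )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthLabels:
    """Ground truth behind one simulated dataset."""

    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    contaminants: set[str] = field(default_factory=set)
    baits: list[str] = field(default_factory=list)
    preys: list[str] = field(default_factory=list)
    planted_complexes: dict[str, str] = field(default_factory=dict)  # id -> bait
    supported_pairs: set[tuple[str, str]] = field(default_factory=set)
    ortholog_groups: list[tuple[frozenset, frozenset]] = field(default_factory=list)

    def true_preys_of(self, bait: str) -> set[str]:
        return {p for b, p in self.true_pairs if b == bait}

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_pairs": sorted(map(list, self.true_pairs)),
                "contaminants": sorted(self.contaminants),
                "baits": self.baits,
                "preys": self.preys,
                "planted_complexes": self.planted_complexes,
                "supported_pairs": sorted(map(list, self.supported_pairs)),
                "ortholog_groups": [
                    [sorted(a), sorted(b)] for a, b in self.ortholog_groups
                ],
            },
            indent=1,
        )


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and dispersion
    (variance = mean + mean^2 / dispersion)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_apms(cfg: SimulationConfig) -> tuple[SpectralCountTable, TruthLabels]:
    """Simulate replicated bait runs and pooled negative-control runs.

    True bait-prey pairs draw counts from the signal distribution;
    contaminant preys draw from the background distribution in bait and
    control runs alike; all other cells are explicit zeros.  Identical
    seeds give identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    baits = [f"{cfg.bait_prefix}{i + 1:02d}" for i in range(cfg.n_baits)]
    preys = [f"{cfg.prey_prefix}{i + 1:04d}" for i in range(cfg.n_preys)]
    n_contam = int(round(cfg.contaminant_fraction * cfg.n_preys))
    contaminants = set(rng.choice(preys, size=n_contam, replace=False).tolist())
    truth = TruthLabels(contaminants=contaminants, baits=baits, preys=preys)

    is_true = rng.random((cfg.n_baits, cfg.n_preys)) < cfg.true_interaction_rate
    rows = []
    for bi, bait in enumerate(baits):
        for pi, prey in enumerate(preys):
            true_pair = bool(is_true[bi, pi])
            contaminant = prey in contaminants
            if not true_pair and not contaminant:
                continue
            if true_pair:
                truth.true_pairs.add((bait, prey))
                counts = _nb(rng, cfg.signal_mean, cfg.signal_dispersion, cfg.replicates)
            else:
                counts = _nb(rng, cfg.background_mean, cfg.background_dispersion, cfg.replicates)
            for r in range(cfg.replicates):
                rows.append((bait, prey, r + 1, int(counts[r])))
    counts_df = pd.DataFrame(rows, columns=["bait", "prey", "replicate", "count"])

    ctrl_rows = []
    for run in range(cfg.n_control_runs):
        for prey in sorted(contaminants):
            ctrl_rows.append(
                (f"ctrl{run + 1:02d}", prey, int(_nb(rng, cfg.background_mean, cfg.background_dispersion, 1)[0]))
            )
    controls_df = pd.DataFrame(ctrl_rows, columns=["run", "prey", "count"])
    table = SpectralCountTable(
        counts_df, controls_df, species=cfg.species, n_replicates=cfg.replicates
    )
    return table, truth


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_scores(
    table: SpectralCountTable, truth: TruthLabels, cfg: SimulationConfig
) -> list[ScoredInteraction]:
    """Score every observed bait-prey pair with the logistic stand-in.

    score = logistic(slope * log2((mean bait count + 1) /
    (mean control count + 1)) - offset); the BFDR column is the empirical
    false-discovery rate of the score ranking against the truth labels,
    made monotone nonincreasing in score (a q-value).
    """
    control_mean = table.control_mean()
    records = []
    for bait in table.baits():
        mat = table.matrix(bait)
        for prey, row in mat.iterrows():
            counts = tuple(float(c) for c in row.to_numpy())
            mb = float(np.mean(counts))
            mc = float(control_mean.get(prey, 0.0))
            fold = np.log2((mb + 1.0) / (mc + 1.0))
            score = float(_logistic(cfg.score_slope * fold - cfg.score_offset))
            records.append((bait, prey, score, counts))
    # empirical-FDR BFDR: cumulative false fraction down the score ranking,
    # then a reverse running minimum to enforce monotonicity
    order = sorted(range(len(records)), key=lambda i: -records[i][2])
    false_flag = np.array(
        [(records[i][0], records[i][1]) not in truth.true_pairs for i in order], dtype=float
    )
    fdr = np.cumsum(false_flag) / np.arange(1, len(order) + 1)
    qval = np.minimum.accumulate(fdr[::-1])[::-1]
    bfdr = np.empty(len(records))
    bfdr[np.array(order)] = np.clip(qval, 0.0, 1.0)
    return [
        ScoredInteraction(bait=b, prey=p, score=s, bfdr=float(bfdr[i]), counts=c)
        for i, (b, p, s, c) in enumerate(records)
    ]


def _connected_edges(
    members: Sequence[str], rng: np.random.Generator, extra_prob: float
) -> frozenset[tuple[str, str]]:
    """Random connected edge set: a random spanning tree plus extras."""
    order = list(rng.permutation(list(members)))
    edges = set()
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        edges.add(tuple(sorted((order[i], order[j]))))
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            if rng.random() < extra_prob:
                edges.add(tuple(sorted((order[i], order[j]))))
    return frozenset(edges)


def plant_complexes(
    truth: TruthLabels, cfg: SimulationConfig, seed: int | None = None
) -> ComplexDatabase:
    """Plant true-interactor-rich complexes among random decoys.

    Each planted complex draws at least ``planted_purity`` of its
    subunits from the true interactors of one bait (baits are cycled) and
    the remainder from other preys; decoys draw uniformly from preys that
    interact with no bait.  Every complex receives a connected random
    intra-complex edge set.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    db = ComplexDatabase()
    all_true_preys = {p for _, p in truth.true_pairs}
    non_interactors = sorted(set(truth.preys) - all_true_preys)
    sizes = rng.integers(
        cfg.complex_size_min, cfg.complex_size_max + 1,
        size=cfg.n_planted_complexes + cfg.n_decoy_complexes,
    )
    for k in range(cfg.n_planted_complexes):
        bait = truth.baits[k % len(truth.baits)]
        pool = sorted(truth.true_preys_of(bait))
        size = int(sizes[k])
        n_true = int(np.ceil(cfg.planted_purity * size))
        if n_true > len(pool):
            raise ValueError(
                f"planted complex needs {n_true} true interactors of {bait}, "
                f"but only {len(pool)} exist; lower the size or purity"
            )
        members = set(rng.choice(pool, size=n_true, replace=False).tolist())
        filler = [p for p in non_interactors if p not in members]
        members |= set(rng.choice(filler, size=size - n_true, replace=False).tolist())
        cid = f"planted{k + 1:02d}"
        db.add(
            ProteinComplex(
                cid, frozenset(members), _connected_edges(sorted(members), rng, cfg.extra_edge_prob),
                source="planted",
            )
        )
        truth.planted_complexes[cid] = bait
    for k in range(cfg.n_decoy_complexes):
        size = int(sizes[cfg.n_planted_complexes + k])
        if size > len(non_interactors):
            raise ValueError(
                f"decoy complex of size {size} exceeds the {len(non_interactors)} "
                "available non-interacting preys"
            )
        members = rng.choice(non_interactors, size=size, replace=False).tolist()
        db.add(
            ProteinComplex(
                f"decoy{k + 1:02d}", frozenset(members),
                _connected_edges(sorted(members), rng, cfg.extra_edge_prob),
                source="decoy",
            )
        )
    return db


def plant_annotations(
    truth: TruthLabels,
    cfg: SimulationConfig,
    detected_pairs: Sequence[tuple[str, str]] | None = None,
    other_truth: TruthLabels | None = None,
    seed: int | None = None,
) -> AnnotationBundle:
    """Plant motif-domain affinity structure, localizations and orthologs.

    A configured fraction of true PPIs receives a matching (motif on
    bait, domain on prey, pair in the affinity table); non-true detected
    pairs receive matches at the (lower) background rate.  Localization
    terms are drawn from the 11-term vocabulary.  When ``other_truth`` is
    supplied (a second simulated species), reciprocal ortholog pairs are
    planted between the two prey namespaces at ``ortholog_coverage`` and
    the planted groups are recorded in both truth objects.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    motif_classes = [f"M{i + 1:02d}" for i in range(6)]
    domain_classes = [f"D{i + 1:02d}" for i in range(18)]
    # one matching domain per motif class; remaining domains are decoys
    affinities = {(m, domain_classes[i]) for i, m in enumerate(motif_classes)}
    bait_motifs: dict[str, set[str]] = {b: set() for b in truth.baits}
    prey_domains: dict[str, set[str]] = {}

    if detected_pairs is None:
        detected_pairs = sorted(truth.true_pairs | {
            (b, p) for b in truth.baits for p in truth.contaminants
        })
    for bait, prey in sorted(detected_pairs):
        is_true = (bait, prey) in truth.true_pairs
        rate = cfg.support_rate_true if is_true else cfg.support_rate_false
        if rng.random() < rate:
            m, d = sorted(affinities)[int(rng.integers(0, len(affinities)))]
            bait_motifs[bait].add(m)
            prey_domains.setdefault(prey, set()).add(d)
            truth.supported_pairs.add((bait, prey))
    # decoy domains on arbitrary preys broaden the background universe
    for prey in truth.preys:
        if rng.random() < 0.3:
            prey_domains.setdefault(prey, set()).add(
                domain_classes[int(rng.integers(len(motif_classes), len(domain_classes)))]
            )

    localizations: dict[str, set[str]] = {}
    for prey in truth.preys:
        if rng.random() < cfg.localization_rate:
            k = int(rng.integers(1, 4))
            terms = rng.choice(LOCALIZATION_TERMS, size=k, replace=False)
            localizations[prey] = set(terms.tolist())

    ortho_rows = []
    if other_truth is not None:
        n_pairs = int(round(cfg.ortholog_coverage * min(len(truth.preys), len(other_truth.preys))))
        mine = rng.choice(truth.preys, size=n_pairs, replace=False)
        theirs = rng.choice(other_truth.preys, size=n_pairs, replace=False)
        for a, b in zip(mine.tolist(), theirs.tolist()):
            score = float(rng.uniform(cfg.min_ortholog_score, cfg.max_ortholog_score))
            ortho_rows.append((a, b, round(score, 1), "forward"))
            ortho_rows.append((a, b, round(score, 1), "reverse"))
            group = (frozenset({a}), frozenset({b}))
            truth.ortholog_groups.append(group)
            other_truth.ortholog_groups.append(group)
    orthologs = pd.DataFrame(
        ortho_rows, columns=["protein_a", "protein_b", "score", "direction"]
    )
    return AnnotationBundle(
        bait_motifs=bait_motifs,
        prey_domains=prey_domains,
        affinities=affinities,
        localizations=localizations,
        orthologs=orthologs,
    )


def evaluate_complex_recovery(results, merged, truth: TruthLabels) -> tuple[float, float]:
    """Sensitivity and empirical FDR of complex associations vs the truth.

    An association (bait, merged complex) is a true positive when the
    merged complex contains a planted source complex whose planted bait
    matches; sensitivity is the fraction of planted complexes recovered
    that way, and the empirical FDR the fraction of passing associations
    that contain no matching planted complex.
    """
    members = {m.merged_id: set(m.members) for m in merged}
    recovered: set[str] = set()
    n_false = 0
    for r in results:
        sources = members.get(r.complex_id, {r.complex_id})
        hits = {cid for cid in sources if truth.planted_complexes.get(cid) == r.bait}
        if hits:
            recovered |= hits
        else:
            n_false += 1
    sensitivity = (
        len(recovered) / len(truth.planted_complexes) if truth.planted_complexes else float("nan")
    )
    fdr = n_false / len(results) if results else 0.0
    return sensitivity, fdr


@dataclass
class SimulatedDataset:
    """One complete synthetic study, ready for the full pipeline."""

    config: SimulationConfig
    table: SpectralCountTable
    scored: list[ScoredInteraction]
    complexes: ComplexDatabase
    annotations: AnnotationBundle
    truth: TruthLabels


def simulate_dataset(
    cfg: SimulationConfig, other_truth: TruthLabels | None = None
) -> SimulatedDataset:
    """Generate counts, scores, complexes and annotations in one call."""
    table, truth = simulate_apms(cfg)
    scored = simulate_scores(table, truth, cfg)
    complexes = plant_complexes(truth, cfg)
    annotations = plant_annotations(
        truth, cfg, detected_pairs=[(s.bait, s.prey) for s in scored], other_truth=other_truth
    )
    return SimulatedDataset(cfg, table, scored, complexes, annotations, truth)
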
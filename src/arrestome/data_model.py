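"""Core domain types and tabular I/O for the AP/MS interactome pipeline.

The pipeline moves spectral-count evidence from affinity-purification /
mass-spectrometry (AP/MS) runs through probabilistic interaction scores
into a high-confidence protein-protein interaction (PPI) network, and then
into enrichment statistics.  This module owns the containers for each of
those stages and the plain-text formats (TSV, GMT) they are exchanged in.

All identifiers (baits, preys, motifs, domains, complexes) are opaque
strings; no species-specific normalisation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "SpectralCountTable",
    "ScoredInteraction",
    "ValidationSets",
    "HighConfidenceNetwork",
    "ProteinComplex",
    "ComplexDatabase",
    "AnnotationBundle",
    "EnrichmentResult",
    "LOCALIZATION_TERMS",
    "read_spectral_counts",
    "write_spectral_counts",
    "read_scores",
    "write_scores",
    "read_complex_gmt",
    "write_complex_gmt",
    "read_complex_edges",
    "read_pair_file",
    "read_annotations",
    "collapse_isoforms",
    "impute_zero_counts",
]


class FormatError(ValueError):
    """A file does not conform to its declared tabular dialect."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


#: The 11 Gene Ontology cellular-component terms used for localization
#: profiles.  Proteins annotated outside this vocabulary are ignored.
LOCALIZATION_TERMS: tuple[str, ...] = (
    "Cytosol",
    "Plasma membrane",
    "Nucleus",
    "Mitochondrion",
    "Endoplasmic reticulum",
    "Golgi apparatus",
    "Cytoskeleton",
    "Peroxisome",
    "Lysosome",
    "Endosome",
    "Extracellular space",
)


class SpectralCountTable:
    """Replicated bait-prey spectral counts plus pooled negative controls.

    Parameters
    ----------
    counts
        DataFrame with columns ``bait, prey, replicate, count``.  The
        (bait, prey, replicate) key must be unique, replicates are numbered
        from 1, and counts are non-negative (integers unless
        ``allow_float`` is set, as after zero imputation).
    controls
        DataFrame with columns ``run, prey, count`` from negative-control
        purifications.  May be empty.
    species
        Free-form label carried through to outputs.
    n_replicates
        Declared number of replicates per bait.  Missing (bait, prey,
        replicate) cells are interpreted as explicit zero counts.
    """

    COUNT_COLUMNS = ("bait", "prey", "replicate", "count")
    CONTROL_COLUMNS = ("run", "prey", "count")

    def __init__(
        self,
        counts: pd.DataFrame,
        controls: pd.DataFrame | None = None,
        species: str = "",
        n_replicates: int = 2,
        allow_float: bool = False,
    ) -> None:
        counts = counts.reset_index(drop=True)[list(self.COUNT_COLUMNS)]
        if controls is None:
            controls = pd.DataFrame(columns=list(self.CONTROL_COLUMNS))
        controls = controls.reset_index(drop=True)[list(self.CONTROL_COLUMNS)]
        self._validate_counts(counts, allow_float)
        self._validate_controls(controls, allow_float)
        if n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        bad_rep = counts[counts["replicate"] > n_replicates]
        if not bad_rep.empty:
            raise ValidationError(
                f"replicate index exceeds declared n_replicates={n_replicates} "
                f"in rows {bad_rep.index.tolist()}"
            )
        self.counts = counts
        self.controls = controls
        self.species = species
        self.n_replicates = int(n_replicates)
        self._is_float = allow_float

    @staticmethod
    def _validate_counts(df: pd.DataFrame, allow_float: bool) -> None:
        dup = df.duplicated(subset=["bait", "prey", "replicate"])
        if dup.any():
            raise ValidationError(
                f"duplicate (bait, prey, replicate) keys at rows {df.index[dup].tolist()}"
            )
        SpectralCountTable._check_count_col(df["count"], allow_float)
        if (df["replicate"] < 1).any():
            rows = df.index[df["replicate"] < 1].tolist()
            raise ValidationError(f"replicate index < 1 at rows {rows}")

    @staticmethod
    def _validate_controls(df: pd.DataFrame, allow_float: bool) -> None:
        SpectralCountTable._check_count_col(df["count"], allow_float)

    @staticmethod
    def _check_count_col(col: pd.Series, allow_float: bool) -> None:
        arr = col.to_numpy()
        if len(arr) == 0:
            return
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count column is not numeric")
        if np.any(arr < 0):
            rows = col.index[col < 0].tolist()
            raise ValidationError(f"negative count at rows {rows}")
        if not allow_float and not np.allclose(arr, np.round(arr)):
            rows = col.index[col != np.round(col)].tolist()
            raise ValidationError(f"non-integer count at rows {rows}")

    # -- convenience views -------------------------------------------------

    def baits(self) -> list[str]:
        return sorted(self.counts["bait"].unique())

    def preys(self) -> list[str]:
        return sorted(self.counts["prey"].unique())

    def matrix(self, bait: str) -> pd.DataFrame:
        """Prey x replicate count matrix for one bait; missing cells are 0."""
        sub = self.counts[self.counts["bait"] == bait]
        mat = sub.pivot_table(
            index="prey", columns="replicate", values="count", aggfunc="sum"
        ).reindex(columns=range(1, self.n_replicates + 1))
        return mat.fillna(0.0)

    def control_mean(self) -> pd.Series:
        """Mean spectral count per prey across control runs (0 if unseen)."""
        if self.controls.empty:
            return pd.Series(dtype=float)
        n_runs = max(self.controls["run"].nunique(), 1)
        return self.controls.groupby("prey")["count"].sum() / n_runs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCountTable):
            return NotImplemented
        key = ["bait", "prey", "replicate"]
        a = self.counts.sort_values(key).reset_index(drop=True)
        b = other.counts.sort_values(key).reset_index(drop=True)
        ca = self.controls.sort_values(["run", "prey"]).reset_index(drop=True)
        cb = other.controls.sort_values(["run", "prey"]).reset_index(drop=True)
        return (
            a.astype({"count": float}).equals(b.astype({"count": float}))
            and ca.astype({"count": float}).equals(cb.astype({"count": float}))
            and self.species == other.species
            and self.n_replicates == other.n_replicates
        )

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class ScoredInteraction:
    """One bait-prey pair with its interaction-probability score.

    ``score`` is a SAINT-style probability of authenticity and ``bfdr`` the
    accompanying Bayesian false discovery rate; both live in [0, 1].
    ``counts`` holds the per-replicate spectral counts for the pair.
    """

    bait: str
    prey: str
    score: float
    bfdr: float
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1] for {self.bait}-{self.prey}")
        if not 0.0 <= self.bfdr <= 1.0:
            raise ValidationError(f"bfdr {self.bfdr} outside [0, 1] for {self.bait}-{self.prey}")
        if any(c < 0 for c in self.counts):
            raise ValidationError(f"negative replicate count for {self.bait}-{self.prey}")


@dataclass(frozen=True)
class ValidationSets:
    """Curated positive and negative PPI pairs used for ROC benchmarking."""

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValidationError(f"pairs in both positive and negative sets: {sorted(overlap)[:5]}")


@dataclass
class HighConfidenceNetwork:
    """Interactions passing the score cutoff and minimum-spectral-count rule."""

    interactions: list[ScoredInteraction]
    score_cutoff: float
    min_spec: int
    species: str = ""

    def baits(self) -> list[str]:
        return sorted({i.bait for i in self.interactions})

    def preys(self) -> list[str]:
        return sorted({i.prey for i in self.interactions})

    def preys_of(self, bait: str) -> set[str]:
        return {i.prey for i in self.interactions if i.bait == bait}

    def score_of(self, bait: str) -> dict[str, float]:
        """Prey -> score map for one bait (absent preys are simply missing)."""
        return {i.prey: i.score for i in self.interactions if i.bait == bait}

    def pairs(self) -> set[tuple[str, str]]:
        return {(i.bait, i.prey) for i in self.interactions}

    def summary(self) -> dict[str, int]:
        return {
            "n_interactions": len(self.interactions),
            "n_baits": len(self.baits()),
            "n_preys": len(self.preys()),
        }

    def __len__(self) -> int:
        return len(self.interactions)


@dataclass(frozen=True)
class ProteinComplex:
    """A named protein set, optionally with its internal interaction edges."""

    complex_id: str
    subunits: frozenset[str]
    edges: frozenset[tuple[str, str]] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValidationError(f"complex {self.complex_id} has an empty subunit set")
        for a, b in self.edges:
            if a not in self.subunits or b not in self.subunits:
                raise ValidationError(
                    f"edge ({a}, {b}) of complex {self.complex_id} references a non-subunit"
                )

    @property
    def size(self) -> int:
        return len(self.subunits)


@dataclass
class ComplexDatabase:
    """Collection of protein complexes from one or more source databases."""

    complexes: dict[str, ProteinComplex] = field(default_factory=dict)

    def add(self, cplx: ProteinComplex) -> None:
        if cplx.complex_id in self.complexes:
            raise ValidationError(f"duplicate complex id {cplx.complex_id}")
        self.complexes[cplx.complex_id] = cplx

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes.values():
            out |= c.subunits
        return out

    @staticmethod
    def pooled(dbs: Iterable["ComplexDatabase"]) -> "ComplexDatabase":
        out = ComplexDatabase()
        for db in dbs:
            for c in db.complexes.values():
                out.add(c)
        return out

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes.values())


@dataclass
class AnnotationBundle:
    """Bait motifs, prey domains, known motif-domain affinities,
    localization terms and cross-species ortholog predictions."""

    bait_motifs: dict[str, set[str]] = field(default_factory=dict)
    prey_domains: dict[str, set[str]] = field(default_factory=dict)
    affinities: set[tuple[str, str]] = field(default_factory=set)
    localizations: dict[str, set[str]] = field(default_factory=dict)
    orthologs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["protein_a", "protein_b", "score", "direction"]
        )
    )
    localization_vocabulary: tuple[str, ...] = LOCALIZATION_TERMS

    def __post_init__(self) -> None:
        motifs = set().union(*self.bait_motifs.values()) if self.bait_motifs else set()
        domains = set().union(*self.prey_domains.values()) if self.prey_domains else set()
        for m, d in self.affinities:
            if motifs and m not in motifs:
                logger.warning("affinity motif %s not in any bait's motif set", m)
            if domains and d not in domains:
                logger.warning("affinity domain %s not in any prey's domain set", d)
        vocab = set(self.localization_vocabulary)
        for prot, terms in self.localizations.items():
            bad = terms - vocab
            if bad:
                raise ValidationError(
                    f"protein {prot} annotated with terms outside the "
                    f"{len(vocab)}-term localization vocabulary: {sorted(bad)}"
                )


@dataclass(frozen=True)
class EnrichmentResult:
    """A statistic with its raw p-value and BH-adjusted q-value.

    ``components`` carries whatever reproduces the statistic: the 2x2
    table of a Fisher test, or the score breakdown of a complex score.
    """

    unit: str
    statistic: float
    p_value: float
    q_value: float
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1] for {self.unit}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(f"q-value {self.q_value} outside [0, 1] for {self.unit}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, required: Sequence[str], colmap: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("bait", "prey", "run")},
        float_precision="round_trip",
    )
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_spectral_counts(
    counts_path,
    controls_path=None,
    species: str = "",
    n_replicates: int | None = None,
    colmap: Mapping[str, str] | None = None,
) -> SpectralCountTable:
    """Read a bait-prey-replicate-count TSV (plus optional control TSV).

    ``colmap`` maps file column names onto the canonical
    ``bait/prey/replicate/count`` (and ``run`` for controls) names.
    Malformed rows are rejected with their row numbers.
    """
    df = _read_tsv(counts_path, SpectralCountTable.COUNT_COLUMNS, colmap)
    for col in ("replicate", "count"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{counts_path}: non-numeric {col} column: {exc}") from None
    controls = None
    if controls_path is not None:
        controls = _read_tsv(controls_path, SpectralCountTable.CONTROL_COLUMNS, colmap)
        controls["count"] = pd.to_numeric(controls["count"])
    if n_replicates is None:
        n_replicates = int(df["replicate"].max()) if len(df) else 2
    return SpectralCountTable(df, controls, species=species, n_replicates=n_replicates)


def write_spectral_counts(table: SpectralCountTable, counts_path, controls_path=None) -> None:
    table.counts.to_csv(counts_path, sep="\t", index=False)
    if controls_path is not None:
        table.controls.to_csv(controls_path, sep="\t", index=False)


def read_scores(path, drop_self: bool = True) -> list[ScoredInteraction]:
    """Read a SAINT-style score table.

    Expected columns: ``bait, prey, score, bfdr`` plus one or more
    ``count_rep<i>`` per-replicate spectral-count columns.  Bait-to-bait
    self-pairs are removed automatically (and logged) unless
    ``drop_self`` is False.
    """
    df = _read_tsv(path, ("bait", "prey", "score", "bfdr"))
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("count_rep")),
        key=lambda c: int(c.removeprefix("count_rep")),
    )
    out: list[ScoredInteraction] = []
    n_self = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        if drop_self and d["bait"] == d["prey"]:
            n_self += 1
            continue
        out.append(
            ScoredInteraction(
                bait=d["bait"],
                prey=d["prey"],
                score=float(d["score"]),
                bfdr=float(d["bfdr"]),
                counts=tuple(float(d[c]) for c in rep_cols),
            )
        )
    if n_self:
        logger.info("removed %d bait-to-bait self-interactions from %s", n_self, path)
    return out


def scores_frame(scored: Sequence[ScoredInteraction]) -> pd.DataFrame:
    """Flatten scored interactions into the canonical wide TSV layout."""
    n_rep = max((len(s.counts) for s in scored), default=0)
    rows = []
    for s in scored:
        row = {"bait": s.bait, "prey": s.prey, "score": s.score, "bfdr": s.bfdr}
        for i in range(n_rep):
            row[f"count_rep{i + 1}"] = s.counts[i] if i < len(s.counts) else 0.0
        rows.append(row)
    cols = ["bait", "prey", "score", "bfdr"] + [f"count_rep{i + 1}" for i in range(n_rep)]
    return pd.DataFrame(rows, columns=cols)


def write_scores(scored: Sequence[ScoredInteraction], path) -> None:
    # %.17g keeps scores/BFDRs bit-exact through the text round trip
    scores_frame(scored).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_complex_gmt(path, source_label: str = "") -> ComplexDatabase:
    """Read a GMT file (name TAB description TAB member...), one complex
    per line.  Duplicate members collapse into the subunit set."""
    db = ComplexDatabase()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and at least one member"
                )
            name = fields[0]
            members = frozenset(m for m in fields[2:] if m)
            db.add(ProteinComplex(name, members, source=source_label))
    return db


def write_complex_gmt(db: ComplexDatabase, path) -> None:
    with open(path, "w") as fh:
        for c in sorted(db, key=lambda c: c.complex_id):
            fh.write("\t".join([c.complex_id, c.source or "na", *sorted(c.subunits)]) + "\n")


def read_complex_edges(db: ComplexDatabase, path) -> ComplexDatabase:
    """Attach intra-complex edges from a TSV (complex_id, subunit_a, subunit_b).

    Returns a new database; edges referencing unknown complexes or
    non-subunits raise."""
    df = _read_tsv(path, ("complex_id", "subunit_a", "subunit_b"))
    by_complex: dict[str, set[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        if row.complex_id not in db.complexes:
            raise ValidationError(f"{path}: edge references unknown complex {row.complex_id}")
        a, b = sorted((row.subunit_a, row.subunit_b))
        by_complex.setdefault(row.complex_id, set()).add((a, b))
    out = ComplexDatabase()
    for cid, c in db.complexes.items():
        out.add(
            ProteinComplex(
                cid, c.subunits, frozenset(by_complex.get(cid, set())) | c.edges, c.source
            )
        )
    return out


def read_pair_file(path, col_a: str = "bait", col_b: str = "prey") -> frozenset[tuple[str, str]]:
    """Read a two-column pair TSV into a frozenset of tuples."""
    df = _read_tsv(path, (col_a, col_b))
    return frozenset(zip(df[col_a].astype(str), df[col_b].astype(str)))


def read_annotations(
    motifs_path=None,
    domains_path=None,
    affinities_path=None,
    localizations_path=None,
    orthologs_path=None,
) -> AnnotationBundle:
    """Assemble an AnnotationBundle from its individual TSV tables."""

    def to_setmap(path, key, val) -> dict[str, set[str]]:
        if path is None:
            return {}
        df = _read_tsv(path, (key, val))
        return {k: set(g[val]) for k, g in df.groupby(key)}

    affinities: set[tuple[str, str]] = set()
    if affinities_path is not None:
        df = _read_tsv(affinities_path, ("motif", "domain"))
        affinities = set(zip(df["motif"], df["domain"]))
    orthologs = pd.DataFrame(columns=["protein_a", "protein_b", "score", "direction"])
    if orthologs_path is not None:
        orthologs = _read_tsv(orthologs_path, ("protein_a", "protein_b", "score", "direction"))
        orthologs["score"] = pd.to_numeric(orthologs["score"])
    return AnnotationBundle(
        bait_motifs=to_setmap(motifs_path, "bait", "motif"),
        prey_domains=to_setmap(domains_path, "prey", "domain"),
        affinities=affinities,
        localizations=to_setmap(localizations_path, "protein", "term"),
        orthologs=orthologs,
    )


# ---------------------------------------------------------------------------
# Count-table transforms
# ---------------------------------------------------------------------------

_REDUCERS: dict[str, Callable] = {"sum": "sum", "max": "max"}


def collapse_isoforms(
    table: SpectralCountTable,
    isoform_map: Mapping[str, str],
    reducer: str = "sum",
) -> SpectralCountTable:
    """Collapse protein isoforms onto their parent gene.

    Prey identifiers are replaced via ``isoform_map`` (identity for preys
    not in the map) and counts of isoforms of the same gene are combined
    per (bait, replicate) with ``reducer`` ("sum", the default, conserves
    total evidence; "max" keeps the dominant isoform).
    """
    if reducer not in _REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}; choose from {sorted(_REDUCERS)}")
    agg = _REDUCERS[reducer]
    counts = table.counts.copy()
    counts["prey"] = counts["prey"].map(lambda p: isoform_map.get(p, p))
    counts = (
        counts.groupby(["bait", "prey", "replicate"], as_index=False)["count"].agg(agg)
    )
    controls = table.controls.copy()
    if not controls.empty:
        controls["prey"] = controls["prey"].map(lambda p: isoform_map.get(p, p))
        controls = controls.groupby(["run", "prey"], as_index=False)["count"].agg(agg)
    return SpectralCountTable(
        counts, controls, table.species, table.n_replicates, allow_float=table._is_float
    )


def impute_zero_counts(table: SpectralCountTable, floor: float = 0.01) -> SpectralCountTable:
    """Replace exact-zero counts by a small positive floor (default 0.01)
    so ratio and correlation computations never divide by zero.  Only the
    zero entries change."""
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    counts = table.counts.copy()
    counts["count"] = counts["count"].astype(float).replace(0.0, floor)
    controls = table.controls.copy()
    if not controls.empty:
        controls["count"] = controls["count"].astype(float).replace(0.0, floor)
    return SpectralCountTable(counts, controls, table.species, table.n_replicates, allow_float=True)
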
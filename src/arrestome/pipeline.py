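"""End-to-end orchestration of the interactome pipeline.

``run_all`` executes the stages in order — simulate (or load) the data,
benchmark and filter the score table, annotate motif-domain support, run
domain enrichment and localization profiles, score protein complexes, and
compare species through ortholog groups — writing one TSV per stage plus
a JSON manifest that captures the config, derived per-stage seeds and
row counts, so an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import complexes as cx
from . import data_model as dm
from . import interactome as net
from . import motif_domain as md
from . import orthologs as ortho
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["stage_seed", "load_config", "run_all"]

_STAGES = ("simulate_a", "simulate_b", "roc", "complexes", "orthologs")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed.

    Uses ``numpy.random.SeedSequence([seed, stage_index])`` so stages can
    be rerun in isolation with the same stream; the result is folded
    below 2**31.
    """
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


_DEFAULTS: dict = {
    "seed": 0,
    "simulate": {},  # SimulationConfig overrides; presence enables synthetic mode
    "cross_species": True,
    "filter": {
        "target_bfdr": 0.01,
        "min_spec": 6,
        "n_cohorts": 1000,
        "sweep_cutoffs": list(range(1, 16)),
    },
    "enrichment": {"ease_q": 0.05},
    "complexes": {
        "n_perm": 1000,
        "screen_p": 0.05,
        "merge_threshold": 0.5,
        "fdr": 0.2,
    },
    "orthologs": {"min_score": 2, "reciprocal": True, "n_bait_clusters": 7},
}


def load_config(path) -> dict:
    """Read and validate a YAML pipeline config against the schema of
    known keys, applying defaults for anything omitted."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}; known keys: {sorted(cfg)}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            unknown = set(val) - set(cfg[key]) if key != "simulate" else set()
            if unknown:
                raise ValueError(f"unknown config key(s) {sorted(unknown)} under {key!r}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["simulate"] is None or not isinstance(cfg["simulate"], dict):
        raise ValueError("config key 'simulate' must be a mapping of SimulationConfig fields")
    known_sim = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
    unknown = set(cfg["simulate"]) - known_sim
    if unknown:
        raise ValueError(f"unknown simulate config field(s) {sorted(unknown)}")
    return cfg


def _validation_from_truth(
    truth: sim.TruthLabels, scored: list[dm.ScoredInteraction]
) -> dm.ValidationSets:
    """Truth-derived benchmark sets: true pairs as positives, detected
    contaminant (non-true) pairs as negatives."""
    detected = {(s.bait, s.prey) for s in scored}
    positives = frozenset(truth.true_pairs & detected)
    negatives = frozenset(detected - truth.true_pairs)
    return dm.ValidationSets(positives=positives, negatives=negatives)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][path.name] = {"rows": int(len(df)), "sha256": _digest(path)}


def _species_stage(
    cfg: dict, species_cfg: sim.SimulationConfig, out: Path, tag: str, manifest: dict
):
    """Simulate one species and run it through filter + enrichment stages."""
    data = sim.simulate_dataset(species_cfg)
    fcfg = cfg["filter"]
    validation = _validation_from_truth(data.truth, data.scored)
    roc = net.build_validation_roc(
        data.scored, validation, n_cohorts=fcfg["n_cohorts"], seed=stage_seed(cfg["seed"], "roc")
    )
    cutoff = net.select_cutoff_by_bfdr(data.scored, target_bfdr=fcfg["target_bfdr"])
    sweep = net.sweep_spectral_cutoff(data.table, cutoffs=fcfg["sweep_cutoffs"])
    network = net.filter_high_confidence(
        data.scored, cutoff, min_spec=fcfg["min_spec"], species=species_cfg.species
    )

    hc_support = md.annotate_supported(network, data.annotations)
    raw_support = md.annotate_supported(
        [(s.bait, s.prey) for s in data.scored], data.annotations
    )
    support = md.support_enrichment_test(hc_support, raw_support)
    background = {s.prey for s in data.scored}
    ease = md.ease_enrichment(network, data.annotations.prey_domains, background)
    loc = md.localization_profile(
        {b: network.preys_of(b) for b in network.baits()}, data.annotations.localizations
    )

    ccfg = cfg["complexes"]
    results, pruned = cx.complex_enrichment_pipeline(
        network,
        [data.complexes],
        n_perm=ccfg["n_perm"],
        seed=stage_seed(cfg["seed"], "complexes"),
        screen_p=ccfg["screen_p"],
        merge_threshold=ccfg["merge_threshold"],
        fdr_cutoff=ccfg["fdr"],
    )

    _write(dm.scores_frame(data.scored), out / f"scores_{tag}.tsv", manifest)
    _write(roc.frame(), out / f"roc_{tag}.tsv", manifest)
    _write(sweep.table, out / f"sweep_{tag}.tsv", manifest)
    _write(dm.scores_frame(network.interactions), out / f"network_{tag}.tsv", manifest)
    _write(md_support_frame(hc_support, support), out / f"support_{tag}.tsv", manifest)
    _write(ease.table, out / f"ease_{tag}.tsv", manifest)
    _write(loc.reset_index(names="bait"), out / f"localization_{tag}.tsv", manifest)
    _write(cx.scores_frame(results, pruned), out / f"complexes_{tag}.tsv", manifest)
    manifest["stages"][tag] = {
        "score_cutoff": cutoff,
        "auc_mean": roc.auc_mean,
        "network": network.summary(),
        "n_complex_associations": len(results),
    }
    return data, network


def md_support_frame(ann: md.SupportAnnotation, result: dm.EnrichmentResult) -> pd.DataFrame:
    rows = [
        {
            "bait": b,
            "prey": p,
            "supported": int(bool(pairs)),
            "pairs": ";".join(f"{m}-{d}" for m, d in sorted(pairs)),
            "fisher_p": result.p_value,
        }
        for (b, p), pairs in sorted(ann.support.items())
    ]
    return pd.DataFrame(rows, columns=["bait", "prey", "supported", "pairs", "fisher_p"])


def run_all(config_path, out_dir) -> dict:
    """Run every pipeline stage from a YAML config; returns the manifest.

    Currently the end-to-end driver runs in synthetic mode: two species
    are simulated (the second with its own prey/bait namespace), each is
    filtered and enriched, and the cross-species stage compares them
    through planted ortholog groups.  Individual stages are available on
    real tables through the CLI subcommands.
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seeds": {s: stage_seed(cfg["seed"], s) for s in _STAGES},
        "outputs": {},
        "stages": {},
    }

    cfg_a = sim.SimulationConfig(**cfg["simulate"]).replace(
        seed=stage_seed(cfg["seed"], "simulate_a")
    )
    data_a, net_a = _species_stage(cfg, cfg_a, out, "a", manifest)

    if cfg["cross_species"]:
        cfg_b = cfg_a.replace(
            seed=stage_seed(cfg["seed"], "simulate_b"),
            species="simB",
            bait_prefix="C",
            prey_prefix="Q",
        )
        data_b, net_b = _species_stage(cfg, cfg_b, out, "b", manifest)
        ann = sim.plant_annotations(
            data_a.truth,
            cfg_a,
            detected_pairs=[(s.bait, s.prey) for s in data_a.scored],
            other_truth=data_b.truth,
            seed=stage_seed(cfg["seed"], "orthologs"),
        )
        ocfg = cfg["orthologs"]
        retained = ortho.filter_orthologs(
            ann.orthologs, min_score=ocfg["min_score"], require_reciprocal=ocfg["reciprocal"]
        )
        groups = ortho.build_ortholog_groups(
            retained, set(net_a.preys()), set(net_b.preys())
        )
        if groups:
            matrix = ortho.build_matrix(groups, data_a.table, data_b.table)
            _write(ortho.groups_frame(groups), out / "ortholog_groups.tsv", manifest)
            _write(matrix.reset_index(names="group_id"), out / "cross_species_matrix.tsv", manifest)
            if matrix.shape[1] >= 2:
                bait_clusters = ortho.cluster(
                    matrix, axis="columns",
                    n_clusters=min(ocfg["n_bait_clusters"], matrix.shape[1]),
                )
                (out / "bait_dendrogram.nwk").write_text(bait_clusters.newick + "\n")
                manifest["outputs"]["bait_dendrogram.nwk"] = {
                    "rows": len(bait_clusters.labels),
                    "sha256": _digest(out / "bait_dendrogram.nwk"),
                }
        manifest["stages"]["orthologs"] = {"n_groups": len(groups)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline complete; outputs in %s", out)
    return manifest
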
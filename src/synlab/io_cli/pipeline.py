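"""End-to-end pipeline: simulate -> (train|oracle) -> attribute -> discover ->
map -> islands -> in-silico syntax analyses; manifest-driven, reproducible."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ..attribution import contribution_scores, discover_motifs, extract_seqlets
from ..core import motif_from_consensus
from ..insilico import distance_sweep, double_cooperativity
from ..mapping import cwm_scan, dedup_instances, pwm_scan
from ..model import Hyperparams, evaluate_model, make_training_set, train_model
from ..sim import make_grammar, oracle_predictor, simulate_genome, simulate_profiles
from ..syntax import build_islands, distance_contributions, pair_table, \
    scan_double_pattern
from .config import RunConfig
from .formats import (write_bedgraph, write_cwm_json, write_fasta,
                      write_instances_bed, write_islands, write_meme,
                      write_truth_bed)

log = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _instance_windows(genome, width: int):
    for inst in genome.truth:
        mid = (inst.start + inst.end) // 2
        lo = mid - width // 2
        if lo >= 0 and lo + width <= len(genome.contigs[inst.contig]):
            yield inst, lo, genome.fetch(inst.contig, lo, lo + width)


def run_pipeline(config: RunConfig, outdir: str,
                 predictor_kind: Optional[str] = None) -> Path:
    """Execute all stages into a run directory; returns its path.

    Any stage failure aborts with the stage name; outputs of completed stages
    persist. A manifest (config, seeds, package version, per-stage timing)
    is written alongside the artifacts.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"version": config.version, "config_hash": config.hash(),
                      "config": config.values, "stages": {}}
    kind = predictor_kind or config["predictor"]
    stage = "init"

    def done(name: str, t0: float, **info):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    try:
        # ---------------------------------------------------------- simulate
        stage = "simulate"
        t0 = time.time()
        grammar = make_grammar(config["grammar"])
        gcfg = config["genome"]
        genome = simulate_genome(grammar, gcfg["n_contigs"], gcfg["contig_len"],
                                 gcfg["density"], gc=gcfg["gc"],
                                 seed=config.seed("genome"),
                                 pair_fraction=gcfg["pair_fraction"],
                                 mismatch_prob=gcfg["mismatch_prob"])
        profiles = simulate_profiles(genome, grammar,
                                     depth=config["profiles"]["depth"],
                                     seed=config.seed("profiles"),
                                     noise=config["profiles"]["noise"])
        write_fasta(out / "genome.fa", genome.contigs)
        write_truth_bed(out / "truth.bed", genome)
        for task in profiles:
            for strand, tag in (("+", "plus"), ("-", "minus")):
                write_bedgraph(out / f"profile_{task}_{tag}.bedGraph",
                               profiles[task], strand)
        done(stage, t0, n_instances=len(genome.truth))

        # --------------------------------------------------------- predictor
        stage = "predictor"
        t0 = time.time()
        if kind == "oracle":
            predictor = oracle_predictor(grammar)
            attribution_width = config["attribution"]["window"]
        elif kind == "trained":
            tcfg = config["training"]
            dataset = make_training_set(genome, profiles, window=tcfg["window"],
                                        background_fraction=tcfg["background_fraction"],
                                        seed=config.seed("training"))
            hp = Hyperparams(filters=tcfg["filters"],
                             learning_rate=tcfg["learning_rate"],
                             batch_size=tcfg["batch_size"],
                             max_epochs=tcfg["max_epochs"],
                             patience=tcfg["patience"])
            predictor, history = train_model(dataset, hp, seed=config.seed("training"))
            predictor.save(str(out / "model"))
            report = evaluate_model(predictor, dataset["test"])
            with open(out / "evaluation.json", "w") as fh:
                json.dump({t: {"counts_spearman": ev.counts_spearman,
                               "jsd_median": ev.jsd_median,
                               "auprc": {str(k): v for k, v in ev.auprc.items()}}
                           for t, ev in report.tasks.items()}, fh, indent=1)
            attribution_width = tcfg["window"]
        else:
            raise ValueError(f"unknown predictor kind {kind!r}")
        done(stage, t0, kind=kind)

        # --------------------------------------------- attribute + discover
        stage = "attribute"
        t0 = time.time()
        acfg = config["attribution"]
        maps_by_task: Dict[str, list] = {}
        boosted_task = grammar.soft_rules[0].task if grammar.soft_rules else \
            grammar.direct_tasks[0]
        for task in grammar.direct_tasks:
            maps_by_task[task] = []
        for inst, lo, seq in _instance_windows(genome, attribution_width):
            task = grammar.motifs[inst.motif_name].task
            for target in {task, boosted_task}:
                cmap = contribution_scores(predictor, seq, target,
                                           n_refs=acfg["n_refs"],
                                           seed=config.seed("attribution"),
                                           contig=inst.contig, start=lo)
                maps_by_task[target].append(cmap)
        done(stage, t0, n_maps=sum(map(len, maps_by_task.values())))

        stage = "discover"
        t0 = time.time()
        seqlets = extract_seqlets([m for ms in maps_by_task.values() for m in ms],
                                  threshold_quantile=acfg["threshold_quantile"])
        dcfg = config["discovery"]
        motifs = discover_motifs(seqlets, min_support=dcfg["min_support"],
                                 max_motifs=dcfg["max_motifs"])
        write_meme(out / "motifs.meme", motifs)
        write_cwm_json(out / "motifs.cwm.json", motifs)
        done(stage, t0, n_seqlets=len(seqlets), n_motifs=len(motifs))

        # -------------------------------------------------------------- scan
        stage = "scan"
        t0 = time.time()
        scan_motifs = motifs or [motif_from_consensus(m.name, m.consensus)
                                 for m in grammar.single_motifs()]
        cwm_hits = []
        for task, maps in maps_by_task.items():
            for cmap in maps:
                for motif in scan_motifs:
                    cwm_hits += cwm_scan(cmap, motif)
        cwm_hits = dedup_instances(cwm_hits)
        write_instances_bed(out / "instances.cwm.bed", cwm_hits)
        pwm_hits = []
        for motif in scan_motifs:
            for contig, seq in genome.contigs.items():
                pwm_hits += pwm_scan(seq, motif, contig=contig)
        pwm_hits = dedup_instances(pwm_hits)
        write_instances_bed(out / "instances.pwm.bed", pwm_hits)
        done(stage, t0, n_cwm=len(cwm_hits), n_pwm=len(pwm_hits))

        # ----------------------------------------------------------- islands
        stage = "islands"
        t0 = time.time()
        islands = build_islands(cwm_hits or list(genome.truth),
                                window=config["islands"]["window"],
                                contig_lengths=genome.contig_lengths())
        write_islands(out / "islands.bed", islands)
        done(stage, t0, n_islands=len(islands))

        # -------------------------------------------------------- doublescan
        stage = "doublescan"
        t0 = time.time()
        table, doubles, singles = scan_double_pattern(
            genome.contigs, config["doublescan"]["pattern"],
            config["doublescan"]["max_gap"])
        pd.DataFrame(sorted(table.counts.items()),
                     columns=["spacing", "count"]).to_csv(
            out / "double_spacings.tsv", sep="\t", index=False)
        write_instances_bed(out / "double_pairs.bed", doubles)
        done(stage, t0, n_pairs=len(doubles))

        # -------------------------------------------------------- injections
        stage = "inject"
        t0 = time.time()
        icfg = config["injection"]
        if grammar.soft_rules:
            rule = grammar.soft_rules[0]
            motifA = next(m for m in grammar.single_motifs()
                          if m.task == rule.task).consensus
            motifB = grammar.motifs[rule.partner].consensus
            sweep = distance_sweep(predictor, motifA, motifB, icfg["distances"],
                                   rule.task, n_backgrounds=icfg["n_backgrounds"],
                                   seed=config.seed("backgrounds"),
                                   window=icfg["window"])
            pd.DataFrame([{"distance": r.distance, "h0": r.h0, "hA": r.hA,
                           "hB": r.hB, "hAB": r.hAB,
                           "enhancement": r.enhancement} for r in sweep]
                         ).to_csv(out / "enhancement_curve.tsv", sep="\t",
                                  index=False)
        done(stage, t0)

        stage = "cooperativity"
        t0 = time.time()
        coop_out = {}
        for rule in grammar.strict_rules:
            dbl = grammar.motifs[rule.name].consensus
            half_w = grammar.motifs[rule.half_site].width
            res = double_cooperativity(predictor, dbl, half_w + rule.spacing,
                                       grammar.motifs[rule.name].task,
                                       n_backgrounds=icfg["n_backgrounds"],
                                       seed=config.seed("backgrounds"),
                                       window=icfg["window"])
            coop_out[rule.name] = {"fold": res.fold, "pred_whole": res.pred_whole,
                                   "pred_additive": res.pred_additive,
                                   "kappa_planted": rule.kappa}
        with open(out / "cooperativity.json", "w") as fh:
            json.dump(coop_out, fh, indent=1)
        done(stage, t0)

        # ---------------------------------------------------- distance stats
        stage = "distance-stats"
        t0 = time.time()
        if grammar.soft_rules:
            rule = grammar.soft_rules[0]
            boosted = [i for i in genome.truth
                       if grammar.motifs[i.motif_name].task == rule.task
                       and grammar.strict_rule_for(i.motif_name) is None]
            partners = [i for i in genome.truth if i.motif_name == rule.partner]
            maps = maps_by_task[rule.task]
            try:
                stats_table = distance_contributions(partners, boosted, maps)
                stats_table.to_csv(out / "distance_contributions.tsv", sep="\t",
                                   index=False)
                pairs = pair_table(partners, boosted, maps)
                pairs.to_csv(out / "distance_pairs.tsv", sep="\t", index=False)
            except ValueError as err:
                log.warning("distance stats skipped: %s", err)
        done(stage, t0)

        manifest["status"] = "complete"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return out
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        manifest["status"] = f"failed at {stage}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise StageFailure(stage, err) from err
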
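"""Top-level driver chaining simulation, preprocessing, behavior,
decoding, RSA and inference into a results directory."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, decoding, image_stats, inference, rsa, synth
from .io import write_epochs, write_rdm, write_timecourse
from .preprocess import PreprocConfig, preprocess_epochs

log = logging.getLogger("facedecode")

ALL_STAGES = ("simulate", "preprocess", "behavior", "imstats", "decode", "rsa", "infer")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    sim: synth.SimConfig = field(default_factory=synth.SimConfig.desk_scale)
    preproc: PreprocConfig | None = None
    bf_accuracy: inference.BFConfig = field(default_factory=inference.BFConfig.for_accuracy)
    bf_correlation: inference.BFConfig = field(default_factory=inference.BFConfig.for_correlation)
    k_extremes: int | None = None  # default: n_stimuli // 4 (200 at full scale: 900//4=225 -> use explicit)
    rdm_metric: str = "cv_decoding"
    n_boot: int = 200
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def resolved_k(self) -> int:
        if self.k_extremes is not None:
            return self.k_extremes
        return max(1, min(200, self.sim.n_stimuli // 4))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "pipeline.log")):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Every stochastic stage derives its stream from ``cfg.seed``, so the
    same config and seed reproduce every output bit for bit.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    from dataclasses import replace

    sim = replace(cfg.sim, seed=cfg.seed)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "numpy": np.__version__,
        "stages": list(cfg.stages),
        "outputs": {},
    }
    timers: dict[str, float] = {}

    def stage(name):
        return name in cfg.stages

    t0 = time.time()
    catalog = synth.make_catalog(sim)
    schedule = synth.build_schedule(sim)

    subjects: list = []
    if stage("simulate"):
        log.info("simulate: %d subjects, %d stimuli, %d trials", sim.n_subjects, sim.n_stimuli, len(schedule))
        catalog.to_csv(out / "catalog.csv", index=False)
        schedule.to_csv(out / "schedule.csv", index=False)
        for s in range(sim.n_subjects):
            epochs, truth = synth.simulate_epochs(catalog, schedule, sim, subject_seed=int(
                np.random.SeedSequence(cfg.seed, spawn_key=(100, s)).generate_state(1)[0] % (2**31)))
            subjects.append(epochs)
            write_epochs(epochs, out / f"sub-{s:02d}")
        truth.save(out / "ground_truth.json")
        timers["simulate"] = time.time() - t0

    if stage("preprocess") and subjects:
        t0 = time.time()
        pp = cfg.preproc or PreprocConfig(crop_window_ms=tuple(sim.epoch_window))
        log.info("preprocess: epoch-level re-reference + detrend + crop")
        subjects = [preprocess_epochs(e, pp) for e in subjects]
        timers["preprocess"] = time.time() - t0

    ratings, scores, splits, rdms = {}, {}, {}, {}
    if stage("behavior"):
        t0 = time.time()
        k = cfg.resolved_k()
        for attr in synth.ATTRIBUTES:
            ratings[attr] = synth.simulate_ratings(catalog, sim, attr)
            ratings[attr].to_csv(out / f"ratings_{attr}.csv", index=False)
            scores[attr] = behavior.aggregate(ratings[attr], expected_ids=catalog["stimulus_id"])
            scores[attr].to_csv(out / f"scores_{attr}.csv", index=False)
            splits[attr] = behavior.select_extremes(scores[attr], k)
            rdms[attr] = behavior.behavioral_rdm(scores[attr])
            write_rdm(rdms[attr], out / f"behavioral_rdm_{attr}.csv")
        rho, p = behavior.correlate_attributes(scores["valence"], scores["sex"])
        json.dump({"spearman_rho": rho, "p": p}, open(out / "attribute_correlation.json", "w"))
        log.info("behavior: k=%d extremes per class; valence-sex rho=%.3f", k, rho)
        timers["behavior"] = time.time() - t0

    if stage("imstats"):
        t0 = time.time()
        images = synth.simulate_images(catalog, sim)
        stat_table = image_stats.image_stat_table(images)
        stat_table.to_csv(out / "image_stats.csv", index=False)
        if splits:
            for attr, split in splits.items():
                image_stats.compare_split(stat_table, split).to_csv(
                    out / f"image_stats_tests_{attr}.csv", index=False)
        timers["imstats"] = time.time() - t0

    decode_results: dict = {}
    pair_tcs: list[np.ndarray] = []
    if stage("decode") and subjects:
        t0 = time.time()
        per_subject_pair = []
        for s, epochs in enumerate(subjects):
            tc = decoding.pairwise_image_decoding(epochs, store_pairs=True)
            per_subject_pair.append(tc)
            pair_tcs.append(tc.pair_accuracy.T.copy())
        group_pair = decoding.group_average(per_subject_pair)
        decode_results["pairwise"] = group_pair
        write_timecourse(group_pair.times, group_pair.subject_stack, out / "decoding_pairwise.csv")
        for attr in splits:
            per_subject = [decoding.class_decoding(e, splits[attr], pairing_seed=cfg.seed) for e in subjects]
            decode_results[attr] = decoding.group_average(per_subject)
            write_timecourse(decode_results[attr].times, decode_results[attr].subject_stack,
                             out / f"decoding_class_{attr}.csv")
        log.info("decode: pairwise + class decoding for %s", sorted(splits))
        timers["decode"] = time.time() - t0

    rsa_results: dict = {}
    if stage("rsa") and subjects and rdms:
        t0 = time.time()
        ids = subjects[0].stimulus_ids()
        if cfg.rdm_metric == "cv_decoding" and pair_tcs:
            subject_rdm_tcs = pair_tcs
        else:
            subject_rdm_tcs = [rsa.neural_rdm_timecourse(e, metric=cfg.rdm_metric)[1] for e in subjects]
        times = subjects[0].times
        human_ids = catalog.loc[catalog["category"] == "human", "stimulus_id"].to_numpy()
        for attr in rdms:
            rsa_results[(attr, "all")] = rsa.rsa_timecourse(
                subject_rdm_tcs, rdms[attr], times, ids, attribute=attr, subset="all")
            rsa_results[(attr, "human")] = rsa.subset_rsa(
                subject_rdm_tcs, rdms[attr], times, ids, human_ids, attribute=attr, subset="human")
            for key in ("all", "human"):
                r = rsa_results[(attr, key)]
                write_timecourse(r.times, r.subject_stack, out / f"rsa_{attr}_{key}.csv", value_name="rho")
        ceiling = rsa.noise_ceiling_lower(subject_rdm_tcs, times)
        pd.DataFrame({"time_ms": times, "noise_ceiling_lower": ceiling}).to_csv(
            out / "noise_ceiling.csv", index=False)
        log.info("rsa: metric=%s, %d pairs", cfg.rdm_metric, subject_rdm_tcs[0].shape[1])
        timers["rsa"] = time.time() - t0

    if stage("infer") and decode_results:
        t0 = time.time()
        summary = {}
        for attr in splits:
            tc = decode_results[attr]
            est = inference.latency(tc.subject_stack, tc.times, 0.5, cfg.bf_accuracy,
                                    n_boot=cfg.n_boot, seed=cfg.seed + 1)
            series = inference.bf_timecourse(tc.subject_stack, tc.times, 0.5, cfg.bf_accuracy)
            pd.DataFrame({"time_ms": tc.times, "bf10": series.bf10, "decision": series.decisions}).to_csv(
                out / f"bf_class_{attr}.csv", index=False)
            summary[attr] = {
                "onset_ms": est.onset_ms,
                "peak_ms": est.peak_ms,
                "peak_accuracy": est.peak_value,
                "ci95_onset": est.ci95_onset,
                "ci95_peak": est.ci95_peak,
            }
        if {"valence", "sex"} <= set(decode_results):
            contrast = inference.bf_paired_contrast(
                decode_results["valence"].subject_stack, decode_results["sex"].subject_stack,
                decode_results["valence"].times, cfg.bf_accuracy)
            pd.DataFrame({"time_ms": contrast.times, "bf10": contrast.bf10,
                          "decision": contrast.decisions}).to_csv(out / "bf_valence_vs_sex.csv", index=False)
        json.dump(summary, open(out / "latency.json", "w"), indent=1)
        log.info("infer: %s", summary)
        timers["infer"] = time.time() - t0

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name == "manifest.json":
            continue
        manifest["outputs"][f.name] = _sha256(f)
    manifest["timers_s"] = {k: round(v, 2) for k, v in timers.items()}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(cfg.sim), sort_keys=True, default=str).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
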
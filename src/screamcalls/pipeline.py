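"""End-to-end orchestration: config validation, staged runs, run manifests.

A run is described by a single YAML config (or an in-memory ``RunConfig``).
Stages execute in dependency order — synth, prep, mps, classify,
alarmsplit, behavior — every source of randomness flows from the config
seed, and each run writes a manifest listing every output file with a
content checksum, so identical configs produce identical manifests.

Default parameters reproduce the study conditions of the scream-call
corpus: 12 speakers x 7 vocalization types x 5 instances (420 clips),
a 420 x 88 feature table with 60 sounds per category, 23 alarm raters,
2000 permutations for the MPS contrast, and 5-fold cross-validation with a
third-order polynomial SVM. ``demo_config`` scales the corpus and
simulation sizes down for a fast end-to-end demonstration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alarm_split, audio_prep, behavior, classify, mps, stats, synth
from .taxonomy import HIGH_ROUGHNESS_BAND, LOW_ROUGHNESS_BAND, SCREAM_TYPES

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline", "demo_config"]

logger = logging.getLogger("screamcalls")

ALL_STAGES = ("synth", "prep", "mps", "classify", "alarmsplit", "behavior")


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    output_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # corpus generation
    n_speakers: int = 12
    instances_per_type: int = 5
    # spectrogram / MPS
    window_sd_s: float = 0.001
    hop_s: float = 0.002
    n_freq_bins: int = 128
    fmin_hz: float = 100.0
    floor_db: float = 80.0
    n_perm: int = 2000
    band_low: tuple[float, float] = LOW_ROUGHNESS_BAND
    band_high: tuple[float, float] = HIGH_ROUGHNESS_BAND
    # feature table / SVM
    n_per_class: int = 60
    n_features: int = 88
    separation: float = 3.0
    n_folds: int = 5
    kernel_degree: int = 3
    # ratings
    n_raters: int = 23
    ratings_per_type: int = 12
    rating_noise_sd: float = 0.1
    # behavior
    n_participants_7afc: int = 33
    n_participants_2afc: int = 35
    trials_per_type_7afc: int = 72
    trials_per_type_2afc: int = 36
    miss_rate_7afc: float = 0.0653
    miss_rate_2afc: float = 0.0155
    response_window_ms: float = 3000.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["band_low"] = list(self.band_low)
        d["band_high"] = list(self.band_high)
        return d


@dataclass(frozen=True)
class RunManifest:
    config: dict
    files: dict[str, str]  # relative path -> sha256
    stage_seconds: dict[str, float]
    warnings: tuple[str, ...]
    version: str

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "files": self.files,
            "stage_seconds": self.stage_seconds,
            "warnings": list(self.warnings),
            "version": self.version,
        }


_FIELD_TYPES: dict[str, type | tuple[type, ...]] = {
    "output_dir": str,
    "seed": int,
    "stages": (list, tuple),
    "n_speakers": int,
    "instances_per_type": int,
    "window_sd_s": (int, float),
    "hop_s": (int, float),
    "n_freq_bins": int,
    "fmin_hz": (int, float),
    "floor_db": (int, float),
    "n_perm": int,
    "band_low": (list, tuple),
    "band_high": (list, tuple),
    "n_per_class": int,
    "n_features": int,
    "separation": (int, float),
    "n_folds": int,
    "kernel_degree": int,
    "n_raters": int,
    "ratings_per_type": int,
    "rating_noise_sd": (int, float),
    "n_participants_7afc": int,
    "n_participants_2afc": int,
    "trials_per_type_7afc": int,
    "trials_per_type_2afc": int,
    "miss_rate_7afc": (int, float),
    "miss_rate_2afc": (int, float),
    "response_window_ms": (int, float),
}


def validate_config_dict(raw: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig; errors name the offending key."""
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "output_dir" not in raw:
        raise ValueError("missing required config key: output_dir")
    for key, value in raw.items():
        expected = _FIELD_TYPES[key]
        if isinstance(value, bool) or not isinstance(value, expected):
            raise ValueError(f"config key {key!r} has invalid type {type(value).__name__}")
    kwargs = dict(raw)
    if "stages" in kwargs:
        stages = tuple(kwargs["stages"])
        bad = set(stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"config key 'stages' contains unknown stage(s): {sorted(bad)}")
        kwargs["stages"] = tuple(s for s in ALL_STAGES if s in stages)
    for band_key in ("band_low", "band_high"):
        if band_key in kwargs:
            band = tuple(float(v) for v in kwargs[band_key])
            if len(band) != 2 or band[0] >= band[1] or band[0] < 0:
                raise ValueError(f"config key {band_key!r} must be an increasing (low, high) pair")
            kwargs[band_key] = band
    return RunConfig(**kwargs)


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config_dict(raw or {})


def demo_config(output_dir: str | Path, seed: int = 0) -> RunConfig:
    """A scaled-down configuration for a fast end-to-end demonstration."""
    return RunConfig(
        output_dir=str(output_dir),
        seed=seed,
        n_speakers=4,
        instances_per_type=2,
        n_perm=300,
        n_per_class=25,
        n_raters=23,
        ratings_per_type=4,
        n_participants_7afc=10,
        n_participants_2afc=10,
        trials_per_type_7afc=24,
        trials_per_type_2afc=10,
    )


def _stage_seed(config: RunConfig, stage: str) -> int:
    idx = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence((config.seed, idx)).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


class _Run:
    """Mutable in-flight state of one pipeline run."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: dict[str, str] = {}
        self.warnings: list[str] = []
        self.corpus: synth.ScreamSet | None = None
        self.prepped: list[audio_prep.AudioClip] | None = None
        self.ratings: alarm_split.RatingTable | None = None
        self.grids: dict[str, mps.MPSGrid] | None = None

    def record(self, path: Path) -> None:
        self.files[str(path.relative_to(self.out))] = _sha256(path)

    # ---- stages -----------------------------------------------------

    def stage_synth(self) -> None:
        cfg = self.config
        design = synth.CorpusDesign(
            n_speakers=cfg.n_speakers,
            instances_per_type=cfg.instances_per_type,
            seed=_stage_seed(cfg, "synth"),
        )
        self.corpus = synth.make_corpus(design)
        clips_dir = self.out / "clips"
        clips_dir.mkdir(exist_ok=True)
        for clip in self.corpus.clips:
            path = clips_dir / f"{clip.clip_id}.wav"
            audio_prep.write_wav(path, clip)
            self.record(path)
        meta_path = self.out / "corpus_metadata.csv"
        self.corpus.metadata.to_csv(meta_path, index=False)
        self.record(meta_path)

        table = synth.make_feature_table(
            n_classes=len(SCREAM_TYPES), n_per_class=cfg.n_per_class,
            n_features=cfg.n_features, separation=cfg.separation,
            seed=_stage_seed(cfg, "synth") + 1,
        )
        feat_path = self.out / "features.csv"
        classify.write_feature_table(feat_path, table)
        self.record(feat_path)

        planted = alarm_split.CategorySplit(
            frozenset({"pain", "fear", "anger"}), frozenset({"pleasure", "sadness", "joy"})
        )
        self.ratings = synth.make_rating_table(
            planted, noise_sd=cfg.rating_noise_sd, n_raters=cfg.n_raters,
            n_per_type=cfg.ratings_per_type, seed=_stage_seed(cfg, "synth") + 2,
        )
        ratings_path = self.out / "alarm_ratings.csv"
        alarm_split.write_rating_table(ratings_path, self.ratings)
        self.record(ratings_path)

        # 7AFC log: mostly correct, with misclassifications biased toward
        # the alarm columns (the decisional pattern the analyses probe).
        k = len(SCREAM_TYPES)
        probs = np.full((k, k), 0.0)
        alarm_idx = [SCREAM_TYPES.index(t) for t in ("pain", "fear", "anger")]
        for i in range(k):
            probs[i, i] = 0.7
            off = [j for j in range(k) if j != i]
            share = np.full(k, 0.0)
            share[off] = 0.3 / len(off)
            for j in alarm_idx:
                if j != i:
                    share[j] *= 2.0
            share[off] *= 0.3 / share[off].sum()
            probs[i] = share
            probs[i, i] = 0.7
        conf = synth.ConfusionSpec(SCREAM_TYPES, probs, miss_rate=cfg.miss_rate_7afc)
        rt7 = synth.RTSpec(
            {t: 1500.0 if t in ("pain", "fear", "anger") else 1200.0 for t in SCREAM_TYPES},
            sigma=0.25, response_window_ms=cfg.response_window_ms,
        )
        log7 = synth.make_afc_log(conf, rt7, cfg.n_participants_7afc,
                                  cfg.trials_per_type_7afc, _stage_seed(cfg, "synth") + 3)
        log7_path = self.out / "afc7_log.csv"
        behavior.write_trial_log(log7_path, log7)
        self.record(log7_path)

        acc = {t: 0.82 if t in ("pain", "fear", "anger") else 0.92 for t in SCREAM_TYPES}
        acc["neutral"] = 0.97
        log2 = synth.make_2afc_log(acc, rt7, cfg.n_participants_2afc,
                                   cfg.trials_per_type_2afc, cfg.miss_rate_2afc,
                                   _stage_seed(cfg, "synth") + 4)
        log2_path = self.out / "afc2_log.csv"
        behavior.write_trial_log(log2_path, log2)
        self.record(log2_path)

    def _require_corpus(self) -> synth.ScreamSet:
        if self.corpus is None:
            raise RuntimeError("synth stage must run before this stage")
        return self.corpus

    def stage_prep(self) -> None:
        corpus = self._require_corpus()
        self.prepped = []
        for clip in corpus.clips:
            cropped = audio_prep.crop_fade(clip, duration_s=clip.duration_s)
            self.prepped.append(audio_prep.normalize_rms(cropped))
        deltas = audio_prep.loudness_delta_table(list(corpus.clips), self.prepped)
        path = self.out / "loudness_deltas.csv"
        deltas.to_csv(path, index=False, float_format="%.10g")
        self.record(path)

        if self.ratings is not None:
            type_means = (
                pd.Series(self.ratings.scream_types)
                .to_frame("scream_type")
                .join(self.ratings.ratings.mean(axis=0).rename("rating"))
                .groupby("scream_type")["rating"].mean()
            )
            clip_types = corpus.metadata.set_index("clip_id")["scream_type"]
            merged = deltas.set_index("clip_id").join(clip_types.map(type_means).rename("rating"))
            corr = stats.pearson(merged["delta_db"].to_numpy(), merged["rating"].to_numpy())
            _write_json(self.out / "loudness_rating_correlation.json",
                        {"r": corr.r, "p_value": corr.p_value, "n": corr.n})
            self.record(self.out / "loudness_rating_correlation.json")

    def stage_mps(self) -> None:
        cfg = self.config
        corpus = self._require_corpus()
        clips = self.prepped if self.prepped is not None else list(corpus.clips)
        self.grids = {}
        for clip in clips:
            spec = mps.spectrogram_log(
                clip, window_sd_s=cfg.window_sd_s, hop_s=cfg.hop_s,
                n_freq_bins=cfg.n_freq_bins, fmin_hz=cfg.fmin_hz, floor_db=cfg.floor_db,
            )
            self.grids[clip.clip_id] = mps.compute_mps(spec)
        bands = mps.band_power_table(self.grids, cfg.band_low, cfg.band_high)
        bands_path = self.out / "band_powers.csv"
        bands.to_csv(bands_path, index_label="clip_id", float_format="%.10g")
        self.record(bands_path)

        meta = corpus.metadata.set_index("clip_id")
        alarm_ids = meta.index[meta.scream_type.isin(["pain", "fear", "anger"])]
        neutral_ids = meta.index[meta.scream_type == "neutral"]
        diff = mps.mps_group_difference(
            [self.grids[i] for i in alarm_ids], [self.grids[i] for i in neutral_ids]
        )
        np.save(self.out / "mps_alarm_vs_neutral_diff.npy", diff)
        self.record(self.out / "mps_alarm_vs_neutral_diff.npy")
        pmap = mps.mps_permutation_pmap(
            [self.grids[i] for i in alarm_ids], [self.grids[i] for i in neutral_ids],
            n_perm=cfg.n_perm, seed=_stage_seed(cfg, "mps"),
        )
        np.save(self.out / "mps_alarm_vs_neutral_pmap.npy", pmap.p_values)
        self.record(self.out / "mps_alarm_vs_neutral_pmap.npy")
        axes = pd.DataFrame({"axis": ["wt"] * len(pmap.wt_axis) + ["ws"] * len(pmap.ws_axis),
                             "value": np.concatenate([pmap.wt_axis, pmap.ws_axis])})
        axes_path = self.out / "mps_axes.csv"
        axes.to_csv(axes_path, index=False, float_format="%.10g")
        self.record(axes_path)

        if self.ratings is not None:
            type_means = (
                pd.Series(self.ratings.scream_types)
                .to_frame("scream_type")
                .join(self.ratings.ratings.mean(axis=0).rename("rating"))
                .groupby("scream_type")["rating"].mean()
            )
            clip_ratings = meta["scream_type"].map(type_means)
            res = mps.alarm_bandpower_regression(bands, clip_ratings)
            _write_json(self.out / "bandpower_regression.json", {
                "beta_low": float(res.coefficients[0]),
                "beta_high": float(res.coefficients[1]),
                "intercept": res.intercept,
                "f_value": res.f_value,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
            })
            self.record(self.out / "bandpower_regression.json")

    def stage_classify(self) -> None:
        cfg = self.config
        feat_path = self.out / "features.csv"
        if not feat_path.exists():
            raise RuntimeError("synth stage must run before classify")
        table = classify.znormalize(classify.read_feature_table(feat_path))
        result = classify.crossval_classify(
            table, n_folds=cfg.n_folds, kernel_degree=cfg.kernel_degree,
            seed=_stage_seed(cfg, "classify"),
        )
        _write_json(self.out / "classification.json", result.to_dict())
        self.record(self.out / "classification.json")

        # cross-classification against a second vocalization corpus drawn
        # from the same class structure (stand-in for nonverbal affect bursts)
        other = synth.make_feature_table(
            n_classes=len(SCREAM_TYPES), n_per_class=max(2, cfg.n_per_class // 2),
            n_features=cfg.n_features, separation=cfg.separation,
            seed=_stage_seed(cfg, "classify") + 1,
        )
        both = classify.cross_classify_both(table, classify.znormalize(other),
                                            kernel_degree=cfg.kernel_degree)
        _write_json(self.out / "cross_classification.json",
                    {k: v.to_dict() for k, v in both.items()})
        self.record(self.out / "cross_classification.json")

    def stage_alarmsplit(self) -> None:
        ratings_path = self.out / "alarm_ratings.csv"
        if self.ratings is None:
            if not ratings_path.exists():
                raise RuntimeError("synth stage must run before alarmsplit")
            self.ratings = alarm_split.read_rating_table(ratings_path)
        scores = alarm_split.best_split(self.ratings)
        alarm_split.write_split_scores(self.out / "alarm_splits.json", scores)
        self.record(self.out / "alarm_splits.json")

    def stage_behavior(self) -> None:
        cfg = self.config
        log7 = behavior.read_trial_log(self.out / "afc7_log.csv", "7AFC",
                                       cfg.response_window_ms)
        conf = behavior.confusion_from_log(log7)
        conf_path = self.out / "confusion_pooled.csv"
        conf.pooled.to_frame().to_csv(conf_path, index_label="true_type")
        self.record(conf_path)
        fa = behavior.false_alarm_rates(conf.pooled)
        fa_path = self.out / "false_alarm_rates.csv"
        fa.to_csv(fa_path, index_label="category", float_format="%.10g")
        self.record(fa_path)
        dp = behavior.dprime_table(conf.pooled)
        dp_path = self.out / "dprime.csv"
        dp.table.to_csv(dp_path, float_format="%.10g")
        self.record(dp_path)
        for name, grouping in (("7level", None), ("3level", behavior.three_level_grouping())):
            summary = behavior.rt_accuracy_summary(log7, grouping)
            path = self.out / f"rt_accuracy_{name}.csv"
            summary.to_csv(path, index=False, float_format="%.10g")
            self.record(path)

        log2 = behavior.read_trial_log(self.out / "afc2_log.csv", "2AFC",
                                       cfg.response_window_ms)
        pairs = behavior.afc2_pairwise(log2)
        pair_rows = [{
            "type_a": p.pair[0], "type_b": p.pair[1],
            "rt_a": p.mean_rt_ms[p.pair[0]], "rt_b": p.mean_rt_ms[p.pair[1]],
            "acc_a": p.mean_accuracy[p.pair[0]], "acc_b": p.mean_accuracy[p.pair[1]],
            "norm_rt_diff": p.norm_rt_diff, "norm_accuracy_diff": p.norm_accuracy_diff,
            "rt_t": p.rt_t, "rt_p": p.rt_p, "rt_p_fdr": p.rt_p_fdr,
            "acc_t": p.acc_t, "acc_p": p.acc_p, "acc_p_fdr": p.acc_p_fdr,
        } for p in pairs]
        pairs_path = self.out / "afc2_pairwise.csv"
        pd.DataFrame(pair_rows).to_csv(pairs_path, index=False, float_format="%.10g")
        self.record(pairs_path)

        combo = behavior.afc2_combo_categories(log2)
        _write_json(self.out / "afc2_combo_anova.json", {
            "class_sizes": combo.class_sizes,
            "rt": {"f_value": combo.rt_anova.f_value, "p_value": combo.rt_anova.p_value,
                   "eta_sq": combo.rt_anova.eta_sq, "corrected": combo.rt_anova.corrected},
            "accuracy": {"f_value": combo.accuracy_anova.f_value,
                         "p_value": combo.accuracy_anova.p_value,
                         "eta_sq": combo.accuracy_anova.eta_sq,
                         "corrected": combo.accuracy_anova.corrected},
        })
        self.record(self.out / "afc2_combo_anova.json")
        combo_path = self.out / "afc2_combo_summary.csv"
        combo.summary.to_csv(combo_path, index=False, float_format="%.10g")
        self.record(combo_path)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages in dependency order and write a manifest."""
    from . import __version__

    run = _Run(config)
    stage_fns = {
        "synth": run.stage_synth,
        "prep": run.stage_prep,
        "mps": run.stage_mps,
        "classify": run.stage_classify,
        "alarmsplit": run.stage_alarmsplit,
        "behavior": run.stage_behavior,
    }
    timings: dict[str, float] = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            import warnings as _warnings

            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                stage_fns[stage]()
            run.warnings.extend(f"{stage}: {w.message}" for w in caught)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", stage, timings[stage])

    manifest = RunManifest(
        config=config.to_dict(),
        files=dict(sorted(run.files.items())),
        stage_seconds=timings,
        warnings=tuple(run.warnings),
        version=__version__,
    )
    _write_json(Path(config.output_dir) / "manifest.json",
                {**manifest.to_dict(), "stage_seconds": {}})
    return manifest
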
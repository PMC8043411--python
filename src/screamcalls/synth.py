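"""Synthetic scream corpora, feature tables, rating tables, and trial logs.

Every downstream analysis stage is testable without the original (private)
recordings because this module plants the exact structure those stages are
built to detect: clips whose envelopes carry band-limited amplitude
modulation in the roughness bands, feature tables with configurable class
separation, alarm-rating tables with a planted alarm/non-alarm partition of
the scream types, and forced-choice trial logs with a configurable
confusion structure, log-normal response times, and a miss rate.

The synthesis model is deliberately minimal: a harmonic carrier (f0 plus 6
harmonics with 1/k amplitudes) multiplied by (1 + depth * band-limited
noise), plus additive broadband noise. The generator is defined by what
the analyses must recover, not by vocal-tract realism. All generators are
pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alarm_split import CategorySplit, RatingTable
from .audio_prep import AudioClip
from .behavior import MISSED, TrialLog
from .classify import FeatureTable
from .taxonomy import SCREAM_TYPES

__all__ = [
    "ScreamSpec",
    "CorpusDesign",
    "ScreamSet",
    "ConfusionSpec",
    "RTSpec",
    "DEFAULT_TYPE_SPECS",
    "make_scream_clip",
    "make_corpus",
    "make_feature_table",
    "make_afc_log",
    "make_2afc_log",
    "make_rating_table",
]

N_HARMONICS = 6


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {message}")


@dataclass(frozen=True)
class ScreamSpec:
    """Parameters of one synthetic scream-like clip."""

    scream_type: str
    duration_s: float = 0.8
    f0_hz: float = 500.0
    am_band: tuple[float, float] | None = None  # (low, high) Hz or None
    am_depth: float = 0.0
    noise_level: float = 0.05
    rate_hz: int = 16000

    def __post_init__(self) -> None:
        _require(self.scream_type in SCREAM_TYPES, "scream_type",
                 f"must be one of {SCREAM_TYPES}")
        _require(self.duration_s > 0, "duration_s", "must be positive")
        _require(0.0 <= self.am_depth <= 1.0, "am_depth", "must lie in [0, 1]")
        _require(self.noise_level >= 0, "noise_level", "must be nonnegative")
        _require(self.rate_hz > 0, "rate_hz", "must be positive")
        top_harmonic = (N_HARMONICS + 1) * self.f0_hz
        _require(self.rate_hz > 2 * self.f0_hz, "rate_hz",
                 "must exceed twice the fundamental")
        _require(self.f0_hz > 0, "f0_hz", "must be positive")
        if self.am_band is not None:
            lo, hi = self.am_band
            _require(lo < hi, "am_band", "low edge must be below high edge")
            _require(lo > 0, "am_band", "band edges must be positive")
            _require(self.rate_hz > 2 * hi, "rate_hz",
                     "must exceed twice the modulation band upper edge")
        # harmonics above Nyquist are simply not synthesized
        del top_harmonic


@dataclass(frozen=True)
class CorpusDesign:
    """Corpus layout: speakers x scream types x instances."""

    n_speakers: int
    types: tuple[str, ...] = field(default=SCREAM_TYPES)
    instances_per_type: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", tuple(self.types))
        _require(self.n_speakers >= 1, "n_speakers", "must be at least 1")
        _require(self.instances_per_type >= 1, "instances_per_type", "must be at least 1")
        _require(len(self.types) >= 1, "types", "must be non-empty")
        _require(len(set(self.types)) == len(self.types), "types", "must be unique")
        unknown = set(self.types) - set(SCREAM_TYPES)
        _require(not unknown, "types", f"unknown scream types {sorted(unknown)}")

    @property
    def n_clips(self) -> int:
        return self.n_speakers * len(self.types) * self.instances_per_type


@dataclass(frozen=True)
class ScreamSet:
    """A generated corpus: one clip per (speaker, type, instance) + metadata."""

    clips: tuple[AudioClip, ...]
    metadata: pd.DataFrame  # clip_id, speaker_id, sex, scream_type, instance

    def clips_of_type(self, scream_type: str) -> list[AudioClip]:
        wanted = set(self.metadata.loc[self.metadata.scream_type == scream_type, "clip_id"])
        return [c for c in self.clips if c.clip_id in wanted]


@dataclass(frozen=True)
class ConfusionSpec:
    """Row-stochastic response-probability matrix for a forced-choice task."""

    categories: tuple[str, ...]
    response_probabilities: np.ndarray  # K x K, rows = true type
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        probs = np.asarray(self.response_probabilities, dtype=float)
        object.__setattr__(self, "response_probabilities", probs)
        k = len(self.categories)
        _require(probs.shape == (k, k), "response_probabilities", f"must be {k}x{k}")
        _require(bool(np.all(probs >= 0)), "response_probabilities",
                 "entries must be nonnegative")
        _require(bool(np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)),
                 "response_probabilities", "rows must sum to 1")
        _require(0.0 <= self.miss_rate < 1.0, "miss_rate", "must lie in [0, 1)")

    @classmethod
    def identity(cls, categories: tuple[str, ...] = SCREAM_TYPES,
                 miss_rate: float = 0.0) -> "ConfusionSpec":
        return cls(categories, np.eye(len(categories)), miss_rate)


@dataclass(frozen=True)
class RTSpec:
    """Log-normal RT family per type: median (ms), log-scale sigma, window."""

    median_ms: dict[str, float]
    sigma: float = 0.3
    response_window_ms: float = 3000.0

    def __post_init__(self) -> None:
        _require(self.sigma > 0, "sigma", "must be positive")
        _require(self.response_window_ms > 0, "response_window_ms", "must be positive")
        for t, m in self.median_ms.items():
            _require(m > 0, "median_ms", f"median for {t!r} must be positive")

    @classmethod
    def uniform(cls, median_ms: float = 1200.0, sigma: float = 0.3,
                response_window_ms: float = 3000.0,
                categories: tuple[str, ...] = SCREAM_TYPES) -> "RTSpec":
        return cls({t: median_ms for t in categories}, sigma, response_window_ms)


def _bandlimited_noise(n: int, band: tuple[float, float], rate: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-peak noise with spectral support confined to the band."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    noise = np.fft.irfft(spectrum, n)
    peak = np.max(np.abs(noise))
    return noise / peak if peak > 0 else noise


def make_scream_clip(spec: ScreamSpec, seed: int) -> AudioClip:
    """Synthesize one clip from its spec; bit-deterministic in (spec, seed)."""
    rng = np.random.default_rng(seed)
    n = round(spec.duration_s * spec.rate_hz)
    t = np.arange(n) / spec.rate_hz
    carrier = np.zeros(n)
    phases = rng.uniform(0, 2 * np.pi, N_HARMONICS + 1)
    for k in range(1, N_HARMONICS + 2):
        f_k = k * spec.f0_hz
        if f_k >= spec.rate_hz / 2:
            break
        carrier += np.sin(2 * np.pi * f_k * t + phases[k - 1]) / k
    if spec.am_band is not None and spec.am_depth > 0:
        envelope = 1.0 + spec.am_depth * _bandlimited_noise(n, spec.am_band, spec.rate_hz, rng)
    else:
        envelope = np.ones(n)
    x = envelope * carrier + spec.noise_level * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return AudioClip(samples=x, rate_hz=spec.rate_hz,
                     metadata={"scream_type": spec.scream_type})


# Per-type synthesis parameters. Neutral is an intense but unmodulated
# vowel-like tone. Roughness (envelope modulation) is characteristic of the
# scream types generally, not of alarm screams alone: pain and fear carry
# strong low-band (near 60 Hz) modulation, anger strong high-band (near
# 160 Hz) modulation, and the non-alarm types carry milder high-band
# modulation — so both bands separate screams from neutral, and modulation
# depth tracks the alarm dimension within each band. The per-type offsets
# beyond the planted bands (f0, noise) are free parameters chosen for
# between-type variety.
DEFAULT_TYPE_SPECS: dict[str, ScreamSpec] = {
    "neutral": ScreamSpec("neutral", f0_hz=300.0, am_band=None, am_depth=0.0),
    "pleasure": ScreamSpec("pleasure", f0_hz=420.0, am_band=(140.0, 180.0), am_depth=0.5),
    "sadness": ScreamSpec("sadness", f0_hz=360.0, am_band=(140.0, 180.0), am_depth=0.4),
    "joy": ScreamSpec("joy", f0_hz=520.0, am_band=(140.0, 180.0), am_depth=0.25),
    "pain": ScreamSpec("pain", f0_hz=600.0, am_band=(50.0, 70.0), am_depth=0.8),
    "fear": ScreamSpec("fear", f0_hz=700.0, am_band=(50.0, 70.0), am_depth=0.8),
    "anger": ScreamSpec("anger", f0_hz=640.0, am_band=(140.0, 180.0), am_depth=0.8),
}


def make_corpus(design: CorpusDesign,
                type_specs: dict[str, ScreamSpec] | None = None) -> ScreamSet:
    """One clip per (speaker, type, instance); speakers alternate sex.

    Male speakers get a lowered fundamental, female speakers a raised one,
    and each instance adds a small deterministic f0 jitter.
    """
    specs = dict(DEFAULT_TYPE_SPECS)
    if type_specs:
        specs.update(type_specs)
    ss = np.random.SeedSequence(design.seed)
    children = iter(ss.spawn(design.n_clips + 1))
    jitter_rng = np.random.default_rng(next(children))
    clips: list[AudioClip] = []
    records: list[dict] = []
    for s in range(design.n_speakers):
        sex = "m" if s % 2 == 0 else "f"
        f0_scale = 0.85 if sex == "m" else 1.15
        for scream_type in design.types:
            base = specs[scream_type]
            for inst in range(design.instances_per_type):
                jitter = float(jitter_rng.uniform(0.95, 1.05))
                spec = ScreamSpec(
                    scream_type=scream_type,
                    duration_s=base.duration_s,
                    f0_hz=base.f0_hz * f0_scale * jitter,
                    am_band=base.am_band,
                    am_depth=base.am_depth,
                    noise_level=base.noise_level,
                    rate_hz=base.rate_hz,
                )
                seed = int(next(children).generate_state(1)[0] % (2**31))
                clip_id = f"spk{s:02d}_{scream_type}_{inst:02d}"
                clip = make_scream_clip(spec, seed)
                clip = AudioClip(
                    samples=clip.samples, rate_hz=clip.rate_hz, clip_id=clip_id,
                    metadata={"speaker_id": f"spk{s:02d}", "sex": sex,
                              "scream_type": scream_type, "instance": inst},
                )
                clips.append(clip)
                records.append({"clip_id": clip_id, "speaker_id": f"spk{s:02d}",
                                "sex": sex, "scream_type": scream_type, "instance": inst})
    return ScreamSet(clips=tuple(clips), metadata=pd.DataFrame(records))


def make_feature_table(n_classes: int, n_per_class: int, n_features: int,
                       separation: float, seed: int) -> FeatureTable:
    """Gaussian class clusters with identity within-class covariance.

    Class means sit on a simplex scaled by ``separation`` (in units of the
    within-class standard deviation): class k's mean is ``separation`` along
    coordinate k, so every pair of class means is separation*sqrt(2) apart.
    """
    for name, v in (("n_classes", n_classes), ("n_per_class", n_per_class),
                    ("n_features", n_features)):
        _require(v >= 1, name, "must be at least 1")
    _require(separation >= 0, "separation", "must be nonnegative")
    _require(n_classes <= n_features, "n_classes",
             "simplex placement needs n_features >= n_classes")
    rng = np.random.default_rng(seed)
    labels = [SCREAM_TYPES[k] if n_classes <= len(SCREAM_TYPES) else f"class{k}"
              for k in range(n_classes)]
    means = np.zeros((n_classes, n_features))
    means[np.arange(n_classes), np.arange(n_classes)] = separation
    values = np.concatenate([
        means[k] + rng.standard_normal((n_per_class, n_features))
        for k in range(n_classes)
    ])
    class_labels = [labels[k] for k in range(n_classes) for _ in range(n_per_class)]
    sound_ids = [f"s{idx:04d}" for idx in range(len(class_labels))]
    feature_names = [f"feat{j:03d}" for j in range(n_features)]
    return FeatureTable(values=values, sound_ids=sound_ids,
                        class_labels=class_labels, feature_names=feature_names)


def _draw_rt(rng: np.random.Generator, median_ms: float, sigma: float,
             window_ms: float) -> float:
    """Log-normal RT truncated at the response window (resampled)."""
    for _ in range(100):
        rt = median_ms * np.exp(sigma * rng.standard_normal())
        if 0 < rt <= window_ms:
            return float(rt)
    return float(window_ms)


def make_afc_log(confusion: ConfusionSpec, rt: RTSpec, n_participants: int,
                 trials_per_type: int, seed: int) -> TrialLog:
    """7AFC trial log with the spec's confusion structure and miss rate."""
    _require(n_participants >= 1, "n_participants", "must be at least 1")
    _require(trials_per_type >= 1, "trials_per_type", "must be at least 1")
    rng = np.random.default_rng(seed)
    cats = confusion.categories
    k = len(cats)
    records = []
    stim = 0
    for p in range(n_participants):
        for i, true_type in enumerate(cats):
            for _ in range(trials_per_type):
                if rng.uniform() < confusion.miss_rate:
                    response, rt_ms = MISSED, np.nan
                else:
                    response = cats[rng.choice(k, p=confusion.response_probabilities[i])]
                    rt_ms = _draw_rt(rng, rt.median_ms[true_type], rt.sigma,
                                     rt.response_window_ms)
                records.append({"participant": f"p{p:02d}", "block": 0,
                                "stimulus_id": f"stim{stim:05d}",
                                "true_type": true_type, "response": response,
                                "rt_ms": rt_ms})
                stim += 1
    return TrialLog(trials=pd.DataFrame(records), task_kind="7AFC",
                    response_window_ms=rt.response_window_ms, categories=cats)


def make_2afc_log(accuracy: dict[str, float] | float, rt: RTSpec,
                  n_participants: int, trials_per_type: int = 36,
                  miss_rate: float = 0.0155, seed: int = 0,
                  categories: tuple[str, ...] = SCREAM_TYPES) -> TrialLog:
    """2AFC block log over all pairs of the 7 categories (21 blocks).

    ``accuracy`` gives the per-type probability of a correct choice (a
    single float applies to every type); errors choose the block's other
    type. One block per unordered pair, ``trials_per_type`` trials of each
    of the two types per participant.
    """
    if isinstance(accuracy, (int, float)):
        accuracy = {t: float(accuracy) for t in categories}
    for t, a in accuracy.items():
        _require(0.0 <= a <= 1.0, "accuracy", f"accuracy for {t!r} must lie in [0, 1]")
    _require(0.0 <= miss_rate < 1.0, "miss_rate", "must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    stim = 0
    pairs = [(a, b) for i, a in enumerate(categories) for b in categories[i + 1:]]
    for block, (t1, t2) in enumerate(pairs):
        for p in range(n_participants):
            order = [t1] * trials_per_type + [t2] * trials_per_type
            for true_type in order:
                other = t2 if true_type == t1 else t1
                if rng.uniform() < miss_rate:
                    response, rt_ms = MISSED, np.nan
                else:
                    correct = rng.uniform() < accuracy[true_type]
                    response = true_type if correct else other
                    rt_ms = _draw_rt(rng, rt.median_ms[true_type], rt.sigma,
                                     rt.response_window_ms)
                records.append({"participant": f"p{p:02d}", "block": block,
                                "stimulus_id": f"stim{stim:05d}",
                                "true_type": true_type, "response": response,
                                "rt_ms": rt_ms})
                stim += 1
    return TrialLog(trials=pd.DataFrame(records), task_kind="2AFC",
                    response_window_ms=rt.response_window_ms, categories=categories)


def make_rating_table(split: CategorySplit, alarm_mean: float = 0.8,
                      nonalarm_mean: float = 0.2, neutral_mean: float = 0.1,
                      noise_sd: float = 0.1, n_raters: int = 23,
                      n_per_type: int = 12, seed: int = 0) -> RatingTable:
    """Alarm ratings with a planted categorization of the scream types.

    Each rating is the type mean plus Gaussian noise, clipped to the
    bounded [0, 1] rating scale.
    """
    for name, v in (("alarm_mean", alarm_mean), ("nonalarm_mean", nonalarm_mean),
                    ("neutral_mean", neutral_mean)):
        _require(0.0 <= v <= 1.0, name, "must lie in [0, 1]")
    _require(noise_sd >= 0, "noise_sd", "must be nonnegative")
    _require(n_raters >= 1, "n_raters", "must be at least 1")
    _require(n_per_type >= 1, "n_per_type", "must be at least 1")
    rng = np.random.default_rng(seed)
    scream_types: dict[str, str] = {}
    means = []
    for t in SCREAM_TYPES:
        if t == "neutral":
            mu = neutral_mean
        elif t in split.alarm_types:
            mu = alarm_mean
        else:
            mu = nonalarm_mean
        for i in range(n_per_type):
            sid = f"{t}_{i:02d}"
            scream_types[sid] = t
            means.append(mu)
    means_arr = np.array(means)
    ratings = np.clip(
        means_arr[None, :] + noise_sd * rng.standard_normal((n_raters, len(means_arr))),
        0.0, 1.0,
    )
    df = pd.DataFrame(ratings, columns=list(scream_types),
                      index=[f"r{i:02d}" for i in range(n_raters)])
    return RatingTable(ratings=df, scream_types=scream_types)
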
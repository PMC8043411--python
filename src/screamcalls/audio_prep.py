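"""Stimulus standardization: RMS normalization, cropping/fading, loudness deltas.

Every clip entering the acoustic analyses is equalized the way the scream
stimuli were prepared: cropped to a fixed duration with short intensity
ramps and scaled to a common RMS level nominally corresponding to 70 dB SPL.
Absolute SPL is not recoverable from digital audio, so the package fixes a
reference convention: a nominal level of 70 dB maps to a digital RMS of
0.05, and other levels scale by 20*log10 around that anchor. All analyses
depend only on clips sharing one RMS, not on the absolute anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "LoudnessDelta",
    "REFERENCE_LEVEL_DB",
    "REFERENCE_RMS",
    "rms",
    "normalize_rms",
    "crop_fade",
    "loudness_delta",
    "loudness_delta_table",
    "read_wav",
    "write_wav",
]

# Reference convention: nominal 70 dB SPL <-> digital RMS 0.05.
REFERENCE_LEVEL_DB = 70.0
REFERENCE_RMS = 0.05


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform with its sampling rate and vocalization metadata."""

    samples: np.ndarray
    rate_hz: int
    clip_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or len(samples) < 1:
            raise ValueError("samples must be a non-empty 1D array")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass(frozen=True)
class LoudnessDelta:
    clip_id: str
    delta_db: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_db):
            raise ValueError("delta_db must be finite")


def rms(clip: AudioClip) -> float:
    return float(np.sqrt(np.mean(clip.samples**2)))


def target_rms_for_level(target_level_db: float) -> float:
    """Digital RMS implied by a nominal dB level under the reference convention."""
    return REFERENCE_RMS * 10.0 ** ((target_level_db - REFERENCE_LEVEL_DB) / 20.0)


def normalize_rms(clip: AudioClip, target_level_db: float = REFERENCE_LEVEL_DB) -> AudioClip:
    """Scale a clip so its RMS matches the target level exactly.

    The waveform shape is unchanged up to a positive scalar. If the scaling
    would push samples beyond +-1 the scaled clip is still returned at the
    exact target RMS and a warning is issued, rather than silently clipping
    (hard clipping would distort the modulation content downstream).
    """
    level = rms(clip)
    if level <= 0:
        raise ValueError("cannot normalize silence")
    scale = target_rms_for_level(target_level_db) / level
    out = clip.samples * scale
    if np.max(np.abs(out)) > 1.0:
        warnings.warn(
            f"clip {clip.clip_id!r}: normalization exceeds full scale "
            f"(peak {np.max(np.abs(out)):.3f}); returned un-clipped",
            stacklevel=2,
        )
    meta = dict(clip.metadata)
    meta["normalized_level_db"] = float(target_level_db)
    return replace(clip, samples=out, metadata=meta)


def crop_fade(clip: AudioClip, duration_s: float = 0.8, ramp_s: float = 0.015) -> AudioClip:
    """Crop to a fixed duration and apply linear intensity ramps at both ends.

    The first and last samples end up exactly at zero amplitude.
    """
    if duration_s <= 0 or ramp_s < 0:
        raise ValueError("duration_s must be positive and ramp_s nonnegative")
    n = round(duration_s * clip.rate_hz)
    if len(clip.samples) < n:
        raise ValueError(
            f"clip of {len(clip.samples)} samples shorter than requested "
            f"{duration_s} s ({n} samples)"
        )
    n_ramp = round(ramp_s * clip.rate_hz)
    if 2 * n_ramp > n:
        raise ValueError("ramps longer than the cropped clip")
    out = clip.samples[:n].copy()
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp)
        out[:n_ramp] *= ramp
        out[-n_ramp:] *= ramp[::-1]
    else:
        out[0] = 0.0
        out[-1] = 0.0
    return replace(clip, samples=out)


def loudness_delta(original: AudioClip, normalized: AudioClip) -> LoudnessDelta:
    """RMS-dB difference between a clip before and after normalization."""
    r_orig, r_norm = rms(original), rms(normalized)
    if r_orig <= 0 or r_norm <= 0:
        raise ValueError("cannot compute loudness delta for silent input")
    return LoudnessDelta(
        clip_id=original.clip_id or normalized.clip_id,
        delta_db=float(20.0 * np.log10(r_orig / r_norm)),
    )


def loudness_delta_table(
    originals: list[AudioClip], normalized: list[AudioClip]
) -> pd.DataFrame:
    """One loudness delta per clip, as a (clip_id, delta_db) table."""
    if len(originals) != len(normalized):
        raise ValueError("clip lists must align")
    deltas = [loudness_delta(o, n) for o, n in zip(originals, normalized)]
    return pd.DataFrame(
        {"clip_id": [d.clip_id for d in deltas], "delta_db": [d.delta_db for d in deltas]}
    )


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a mono 32-bit float RIFF WAV file."""
    wavfile.write(str(path), clip.rate_hz, clip.samples.astype(np.float32))


def read_wav(path: str | Path, clip_id: str | None = None) -> AudioClip:
    """Read a mono WAV file; integer PCM is rescaled to [-1, 1] floats."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioClip(
        samples=data, rate_hz=int(rate), clip_id=clip_id or Path(path).stem
    )
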
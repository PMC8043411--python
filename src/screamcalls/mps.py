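"""Modulation power spectrum analysis of vocalizations.

A clip is first converted to a log-amplitude spectrogram using Gaussian
analysis windows and a log-spaced frequency axis. The modulation power
spectrum (MPS) is the squared magnitude of the 2D Fourier transform of the
mean-removed log-spectrogram: its axes are the Fourier pairs of the
spectrogram's time axis (temporal modulation, Hz) and log-frequency axis
(spectral modulation, cycles/octave). The grid is truncated at 200 Hz and
12 cycles/octave.

Scream-like vocalizations carry temporal-modulation ("roughness") energy in
two bands, near 60 Hz (50-70) and near 160 Hz (140-180). Band power is the
mean MPS power over |temporal modulation| within a band, across the full
spectral-modulation range. Group contrasts against neutral vocalizations
use a per-bin mean difference with a label-shuffling permutation null.

Spectrogram defaults: Gaussian window SD 1 ms, hop 2 ms, 128 log-spaced
bins from 100 Hz. The hop puts the temporal-modulation Nyquist at 250 Hz,
above the 200 Hz truncation bound, and the window SD keeps the window's
temporal modulation transfer (a Gaussian of SD 1/(2*pi*sigma) ~ 159 Hz)
open across both roughness bands -- a long window would low-pass the
envelope and erase exactly the modulations this analysis quantifies, at
the price of coarse spectral resolution, the usual trade-off in
modulation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import gaussian as gaussian_window

from . import stats
from .audio_prep import AudioClip
from .taxonomy import HIGH_ROUGHNESS_BAND, LOW_ROUGHNESS_BAND

__all__ = [
    "Spectrogram",
    "MPSGrid",
    "PermutationMap",
    "spectrogram_log",
    "compute_mps",
    "band_power",
    "band_power_table",
    "mps_group_difference",
    "mps_permutation_pmap",
    "alarm_bandpower_regression",
]

WT_MAX_HZ = 200.0
WS_MAX_CYC_PER_OCT = 12.0


@dataclass(frozen=True)
class Spectrogram:
    """Log-amplitude spectrogram: time x log-spaced frequency."""

    values: np.ndarray  # time x frequency, log amplitude (dB)
    time_axis: np.ndarray  # seconds, uniform step
    freq_axis: np.ndarray  # Hz, log-spaced

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.time_axis), len(self.freq_axis)):
            raise ValueError("values shape must match axes")
        for ax in (self.time_axis, self.freq_axis):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")

    @property
    def time_step_s(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    @property
    def octaves_per_bin(self) -> float:
        return float(np.log2(self.freq_axis[-1] / self.freq_axis[0]) / (len(self.freq_axis) - 1))


@dataclass(frozen=True)
class MPSGrid:
    """MPS power over (spectral modulation x temporal modulation).

    ``power[i, j]`` is the power at spectral modulation ``ws_axis[i]``
    (cycles/octave, >= 0) and temporal modulation ``wt_axis[j]`` (Hz,
    spanning negative to positive rates).
    """

    power: np.ndarray
    wt_axis: np.ndarray
    ws_axis: np.ndarray

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.ws_axis), len(self.wt_axis)):
            raise ValueError("power shape must match (ws, wt) axes")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if self.ws_axis.min() < 0:
            raise ValueError("spectral modulation axis must be nonnegative")
        if self.wt_axis.max() > WT_MAX_HZ + 1e-9:
            raise ValueError(f"temporal modulation axis exceeds {WT_MAX_HZ} Hz bound")
        if self.ws_axis.max() > WS_MAX_CYC_PER_OCT + 1e-9:
            raise ValueError(
                f"spectral modulation axis exceeds {WS_MAX_CYC_PER_OCT} cyc/oct bound"
            )


@dataclass(frozen=True)
class PermutationMap:
    """Per-bin two-sided permutation p-values for a group contrast."""

    p_values: np.ndarray
    wt_axis: np.ndarray
    ws_axis: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_perm + 1)
        if np.any(self.p_values < lo - 1e-12) or np.any(self.p_values > 1 + 1e-12):
            raise ValueError("permutation p-values must lie in [1/(n_perm+1), 1]")


def spectrogram_log(
    clip: AudioClip,
    window_sd_s: float = 0.001,
    hop_s: float = 0.002,
    n_freq_bins: int = 128,
    fmin_hz: float = 100.0,
    fmax_hz: float | None = None,
    floor_db: float = 80.0,
) -> Spectrogram:
    """Gaussian-window log-amplitude spectrogram on a log frequency axis.

    The short-time transform uses a Gaussian window of the given standard
    deviation (support +-4 SD); magnitudes on the linear FFT grid are
    interpolated onto ``n_freq_bins`` log-spaced frequencies and converted
    to dB, floored at ``floor_db`` below the clip maximum.
    """
    fs = clip.rate_hz
    if fmax_hz is None:
        fmax_hz = min(8000.0, fs / 2.0)
    if not (0 < fmin_hz < fmax_hz <= fs / 2.0):
        raise ValueError("need 0 < fmin_hz < fmax_hz <= rate/2")
    if window_sd_s <= 0 or hop_s <= 0:
        raise ValueError("window_sd_s and hop_s must be positive")
    if n_freq_bins < 2:
        raise ValueError("n_freq_bins must be at least 2")
    if floor_db <= 0:
        raise ValueError("floor_db must be positive")

    sd_samples = window_sd_s * fs
    m = int(round(8 * sd_samples)) | 1  # odd support of +-4 SD
    hop = max(1, round(hop_s * fs))
    win = gaussian_window(m, std=sd_samples)
    sft = ShortTimeFFT(win, hop=hop, fs=fs)
    spec = np.abs(sft.stft(clip.samples))  # freq x frames (zero-padded edges)
    lin_freqs = sft.f

    log_freqs = np.geomspace(fmin_hz, fmax_hz, n_freq_bins)
    # linear interpolation of magnitude onto the log-spaced axis, per frame
    mag = np.empty((n_freq_bins, spec.shape[1]))
    for j in range(spec.shape[1]):
        mag[:, j] = np.interp(log_freqs, lin_freqs, spec[:, j])

    peak = mag.max()
    if peak <= 0:
        values = np.full(mag.T.shape, -floor_db)
    else:
        floor_amp = peak * 10.0 ** (-floor_db / 20.0)
        values = 20.0 * np.log10(np.maximum(mag.T, floor_amp))
    time_axis = np.arange(spec.shape[1]) * (hop / fs)
    return Spectrogram(values=values, time_axis=time_axis, freq_axis=log_freqs)


def _mps_full(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Untruncated MPS: power normalized so total power satisfies Parseval
    (sum of power = squared norm of the mean-removed log-spectrogram)."""
    x = spec.values - spec.values.mean()
    f2 = np.fft.fft2(x)  # axis 0: time -> temporal modulation; axis 1: freq -> spectral
    power = np.abs(f2) ** 2 / x.size
    wt = np.fft.fftshift(np.fft.fftfreq(x.shape[0], d=spec.time_step_s))
    ws = np.fft.fftshift(np.fft.fftfreq(x.shape[1], d=spec.octaves_per_bin))
    power = np.fft.fftshift(power)
    return power.T, wt, ws  # transpose -> (ws, wt)


def compute_mps(
    spec: Spectrogram,
    wt_max: float = WT_MAX_HZ,
    ws_max: float = WS_MAX_CYC_PER_OCT,
) -> MPSGrid:
    """MPS of a log-spectrogram, truncated to the modulation bounds.

    The mean of the log-spectrogram is removed before the 2D transform so
    the DC bin does not dominate. The nonnegative spectral-modulation
    half-plane is kept (the full plane is Hermitian-redundant for real
    input); the temporal-modulation axis keeps both signs.
    """
    if spec.values.shape[0] < 2 or spec.values.shape[1] < 2:
        raise ValueError("spectrogram needs at least 2 frames and 2 frequency bins")
    power, wt, ws = _mps_full(spec)
    keep_ws = (ws >= 0) & (ws <= ws_max + 1e-12)
    keep_wt = np.abs(wt) <= wt_max + 1e-12
    return MPSGrid(
        power=power[np.ix_(keep_ws, keep_wt)], wt_axis=wt[keep_wt], ws_axis=ws[keep_ws]
    )


def band_power(mps: MPSGrid, wt_lo: float, wt_hi: float) -> float:
    """Mean MPS power over |temporal modulation| in [wt_lo, wt_hi] Hz."""
    if not (0 <= wt_lo < wt_hi):
        raise ValueError("need 0 <= wt_lo < wt_hi")
    if wt_hi > mps.wt_axis.max() + 1e-9:
        raise ValueError(f"band ({wt_lo}, {wt_hi}) outside grid bound {mps.wt_axis.max():.1f} Hz")
    mask = (np.abs(mps.wt_axis) >= wt_lo) & (np.abs(mps.wt_axis) <= wt_hi)
    if not mask.any():
        raise ValueError("band contains no grid bins")
    return float(mps.power[:, mask].mean())


def band_power_table(
    grids: dict[str, MPSGrid],
    low_band: tuple[float, float] = LOW_ROUGHNESS_BAND,
    high_band: tuple[float, float] = HIGH_ROUGHNESS_BAND,
) -> pd.DataFrame:
    """Low- and high-band roughness power for a set of clips (rows = clip ids)."""
    rows = {
        clip_id: {
            "low_band_power": band_power(g, *low_band),
            "high_band_power": band_power(g, *high_band),
        }
        for clip_id, g in grids.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _check_congruent(grids: list[MPSGrid]) -> np.ndarray:
    if not grids:
        raise ValueError("empty group")
    shape = grids[0].power.shape
    for g in grids[1:]:
        if g.power.shape != shape:
            raise ValueError("MPS grids are not congruent")
    return np.stack([g.power for g in grids])


def mps_group_difference(group_a: list[MPSGrid], group_b: list[MPSGrid]) -> np.ndarray:
    """Element-wise mean(a) - mean(b) over congruent grids."""
    a = _check_congruent(group_a)
    b = _check_congruent(group_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("MPS grids are not congruent across groups")
    return a.mean(axis=0) - b.mean(axis=0)


def mps_permutation_pmap(
    group_a: list[MPSGrid],
    group_b: list[MPSGrid],
    n_perm: int = 2000,
    seed: int = 0,
) -> PermutationMap:
    """Per-bin permutation test of the group mean difference.

    Group labels are shuffled over the pooled grids (group sizes
    preserved); the two-sided p-value per bin uses the add-one estimator
    p = (1 + #{|perm diff| >= |observed|}) / (n_perm + 1), so p is never
    exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    a = _check_congruent(group_a)
    b = _check_congruent(group_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("MPS grids are not congruent across groups")
    n_a = a.shape[0]
    pooled = np.concatenate([a, b]).reshape(n_a + b.shape[0], -1)
    n = pooled.shape[0]
    observed = np.abs(pooled[:n_a].mean(axis=0) - pooled[n_a:].mean(axis=0))

    rng = np.random.default_rng(seed)
    # weights turning a permuted stack into a mean difference
    w = np.full(n, -1.0 / (n - n_a))
    w[:n_a] = 1.0 / n_a
    exceed = np.zeros(pooled.shape[1], dtype=int)
    batch = max(1, min(n_perm, 512))
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(m)])
        diffs = np.abs(w[np.argsort(perms, axis=1)] @ pooled)
        exceed += (diffs >= observed[None, :] - 1e-15).sum(axis=0)
        done += m
    p = (1.0 + exceed) / (n_perm + 1.0)
    ref = group_a[0]
    return PermutationMap(
        p_values=p.reshape(ref.power.shape),
        wt_axis=ref.wt_axis,
        ws_axis=ref.ws_axis,
        n_perm=n_perm,
        seed=seed,
    )


def alarm_bandpower_regression(
    band_powers: pd.DataFrame, ratings: pd.Series
) -> stats.RegressionResult:
    """OLS of per-scream mean alarm ratings on the two roughness band powers.

    ``band_powers`` must have columns low_band_power and high_band_power
    indexed by scream id; ``ratings`` is the mean alarm rating per scream.
    """
    required = {"low_band_power", "high_band_power"}
    if not required <= set(band_powers.columns):
        raise ValueError(f"band_powers needs columns {sorted(required)}")
    common = band_powers.index.intersection(ratings.index)
    if len(common) < 3:
        raise ValueError("need at least 3 screams present in both inputs")
    if len(common) < len(band_powers) or len(common) < len(ratings):
        missing = set(band_powers.index) ^ set(ratings.index)
        raise ValueError(f"scream ids do not match between inputs: {sorted(missing)[:5]}")
    X = band_powers.loc[common, ["low_band_power", "high_band_power"]].to_numpy()
    y = ratings.loc[common].to_numpy(dtype=float)
    return stats.ols(X, y, predictor_names=("low_band_power", "high_band_power"))
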
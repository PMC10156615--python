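"""Spectro-temporal modulation analysis of audio and ROI-rating correlation.

The representation used here is a simplified auditory-cortical model: a
128-channel constant-Q filterbank on a 24-bin-per-octave grid referenced to
440 Hz, whose framed log-compressed envelopes are decomposed -- via a
windowed 2-D Fourier transform over (channel, time) -- into energy at 7
spectral-modulation scales (0.125-8 cycles/octave) and 12 signed temporal
modulation rates (+/- 1-32 Hz), keeping the frequency axis so that the
4-D (frequency x scale x rate x time) array supports region-of-interest
extraction.  The ROI previously linked to sound unpleasantness is the mean
intensity over 2500-5500 Hz and 1-16 Hz temporal-modulation magnitudes
(averaging over time and spectral modulations).

Per-sound ROI energies are correlated with mean ratings by Spearman's rho,
with one-tailed critical values computed either exactly (full enumeration of
rank permutations, feasible for n <= 10) or by the Student-t approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import chain, permutations
from math import factorial

import numpy as np
from scipy import stats

from .audio import Waveform

__all__ = [
    "N_CHANNELS",
    "SPECTRAL_MOD_BINS",
    "TEMPORAL_MOD_BINS",
    "channel_centres",
    "channel_edges",
    "auditory_spectrogram",
    "modulation_energy",
    "cortical_representation",
    "CorticalRepresentation",
    "RoiSpec",
    "roi_energy",
    "correlate_roi_ratings",
    "RoiCorrelation",
    "spearman_critical_value",
]

N_CHANNELS = 128
BINS_PER_OCTAVE = 24
REFERENCE_HZ = 440.0
FRAME_S = 0.005

SPECTRAL_MOD_BINS = np.array([0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0])  # cyc/oct
TEMPORAL_MOD_MAGNITUDES = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])  # Hz
# Signed rate bins ordered -32 .. -1, +1 .. +32.
TEMPORAL_MOD_BINS = np.concatenate(
    [-TEMPORAL_MOD_MAGNITUDES[::-1], TEMPORAL_MOD_MAGNITUDES]
)


def channel_edges() -> np.ndarray:
    """The 129 edge frequencies 440 * 2^((k - 31)/24), k = 0..128.

    Edge index 31 is exactly the 440 Hz reference.
    """
    k = np.arange(N_CHANNELS + 1)
    return REFERENCE_HZ * 2.0 ** ((k - 31) / BINS_PER_OCTAVE)


def channel_centres() -> np.ndarray:
    """128 filterbank centre frequencies: geometric midpoints of the edges.

    Equivalent to 440 * 2^((k - 30.5)/24) for k = 0..127, spanning ~182 to
    ~7142 Hz (5.3 octaves at 24 bins per octave, referenced to 440 Hz).
    """
    k = np.arange(N_CHANNELS)
    return REFERENCE_HZ * 2.0 ** ((k - 30.5) / BINS_PER_OCTAVE)


# ----------------------------------------------------------------------
# Front end: constant-Q envelope spectrogram


def auditory_spectrogram(w: Waveform, frame_s: float = FRAME_S) -> np.ndarray:
    """Constant-Q filterbank envelope matrix (128 channels x time frames).

    Each channel is a Gaussian band-pass filter centred on the 24-per-octave
    grid with FWHM equal to one channel spacing; the analytic-signal
    envelope is averaged within ``frame_s`` frames (default 5 ms).  Output
    is non-negative.
    """
    fc = channel_centres()
    min_sr = 2.0 * fc[-1]
    if w.sample_rate < min_sr:
        raise ValueError(
            f"sample rate {w.sample_rate} Hz too low for the filterbank; "
            f"need at least {min_sr:.0f} Hz"
        )
    n = w.n_samples
    frame_len = max(1, int(round(frame_s * w.sample_rate)))
    n_frames = n // frame_len
    if n_frames < 1:
        raise ValueError("waveform shorter than one analysis frame")

    X = np.fft.fft(w.samples)
    f = np.fft.fftfreq(n, 1.0 / w.sample_rate)
    pos = f > 0
    fpos = f[pos]
    # FWHM = one channel spacing -> sigma via the Gaussian FWHM relation
    sigma = fc * (2.0 ** (1.0 / BINS_PER_OCTAVE) - 1.0) / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    out = np.empty((N_CHANNELS, n_frames))
    chunk = 16
    for lo in range(0, N_CHANNELS, chunk):
        hi = min(lo + chunk, N_CHANNELS)
        H = np.zeros((hi - lo, n))
        H[:, pos] = 2.0 * np.exp(
            -0.5 * ((fpos[None, :] - fc[lo:hi, None]) / sigma[lo:hi, None]) ** 2
        )
        env = np.abs(np.fft.ifft(H * X[None, :], axis=1))
        out[lo:hi] = env[:, : n_frames * frame_len].reshape(
            hi - lo, n_frames, frame_len
        ).mean(axis=2)
    return out


# ----------------------------------------------------------------------
# Modulation decomposition


@dataclass
class CorticalRepresentation:
    """4-D intensity array: frequency x spectral mod x temporal mod x time."""

    intensity: np.ndarray  # (128, 7, 12, n_windows); energy density per bin
    cell_counts: np.ndarray | None = None  # (7, 12) FFT cells per bin
    channel_centres_hz: np.ndarray = field(default_factory=channel_centres)
    spectral_mod_bins: np.ndarray = field(default_factory=lambda: SPECTRAL_MOD_BINS.copy())
    temporal_mod_bins: np.ndarray = field(default_factory=lambda: TEMPORAL_MOD_BINS.copy())
    frame_s: float = FRAME_S
    window_s: float = 4.0
    hop_s: float = 2.0

    def __post_init__(self):
        s = self.intensity.shape
        if len(s) != 4 or s[0] != len(self.channel_centres_hz) or s[1] != 7 or s[2] != 12:
            raise ValueError(f"intensity must be (channels, 7, 12, time); got {s}")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.intensity.shape[3]

    def rate_marginal(self) -> np.ndarray:
        """Mean intensity per signed temporal-modulation bin."""
        return self.intensity.mean(axis=(0, 1, 3))

    def scale_marginal(self) -> np.ndarray:
        return self.intensity.mean(axis=(0, 2, 3))


def _bin_assignment(n_ch: int, n_t: int, frame_s: float) -> np.ndarray:
    """Map each 2-D FFT cell to a (scale, rate) bin index, -1 for DC.

    Scales use |spectral frequency| with nearest-bin assignment on the log2
    grid (clamped at the ends, so e.g. 64 Hz temporal content lands in the
    32 Hz bin).  Rates keep a sign: for cells in the upper half-plane
    (spectral frequency >= 0) the temporal sign is kept, in the lower
    half-plane it is flipped, which separates upward- from downward-moving
    ripples.  Pure temporal cells (spectral frequency 0) go to the lowest
    scale bin.  The whole temporal-DC column (temporal frequency 0 --
    static spectral structure, including the DC cell) is excluded: a sound's
    stationary spectral profile is not temporal modulation.
    """
    om_s = np.fft.fftfreq(n_ch, d=1.0 / BINS_PER_OCTAVE)  # cyc/oct
    om_t = np.fft.fftfreq(n_t, d=frame_s)  # Hz
    OmS, OmT = np.meshgrid(om_s, om_t, indexing="ij")

    log_scale_bins = np.log2(SPECTRAL_MOD_BINS)
    log_rate_bins = np.log2(TEMPORAL_MOD_MAGNITUDES)

    abs_s = np.abs(OmS)
    with np.errstate(divide="ignore"):
        ls = np.log2(np.where(abs_s > 0, abs_s, SPECTRAL_MOD_BINS[0]))
    scale_idx = np.abs(ls[..., None] - log_scale_bins).argmin(axis=-1)

    signed_rate = np.where(OmS >= 0, OmT, -OmT)
    abs_r = np.abs(signed_rate)
    with np.errstate(divide="ignore"):
        lr = np.log2(np.where(abs_r > 0, abs_r, TEMPORAL_MOD_MAGNITUDES[0]))
    mag_idx = np.abs(lr[..., None] - log_rate_bins).argmin(axis=-1)
    positive = signed_rate >= 0
    n_mag = len(TEMPORAL_MOD_MAGNITUDES)
    rate_idx = np.where(positive, n_mag + mag_idx, n_mag - 1 - mag_idx)

    flat = scale_idx * 12 + rate_idx
    flat[OmT == 0] = -1  # static spectral structure (incl. DC) excluded
    return flat


def modulation_energy(
    spec: np.ndarray,
    frame_s: float = FRAME_S,
    window_s: float = 4.0,
    hop_s: float = 2.0,
    floor: float = 1e-4,
) -> CorticalRepresentation:
    """Windowed 2-D modulation decomposition of an envelope spectrogram.

    Each window of the log-compressed spectrogram (``log1p(spec/floor)``,
    mean removed) is Fourier transformed over (channel, time); energy is
    routed to the 7 x 12 (scale, signed rate) bins by masking the transform
    per bin and inverting, which preserves the per-channel axis.  Reported
    intensity is energy *density*: per-bin energy divided by the number of
    FFT cells the bin covers (so bins of different log-width are
    comparable, as the outputs of equal-gain modulation filters would be),
    averaged over frames within the window.  The bin masks partition every
    cell outside the temporal-DC column, so summing density * cell count
    over bins recovers the variance of the non-static part of the window
    (Parseval).
    """
    spec = np.asarray(spec, dtype=float)
    n_ch, n_frames = spec.shape
    if n_frames * frame_s < 2.0:
        raise ValueError(
            f"input too short for modulation analysis: {n_frames * frame_s:.3f} s "
            "of frames, need at least 2 s for the 1 Hz bin to be resolvable"
        )
    win = min(n_frames, int(round(window_s / frame_s)))
    hop = max(1, int(round(hop_s / frame_s)))
    starts = list(range(0, n_frames - win + 1, hop)) or [0]

    y = np.log1p(spec / floor)
    assign = _bin_assignment(n_ch, win, frame_s)
    masks = [assign == b for b in range(7 * 12)]
    counts = np.array([int(m.sum()) for m in masks])

    intensity = np.empty((n_ch, 7, 12, len(starts)))
    for wi, s0 in enumerate(starts):
        yw = y[:, s0 : s0 + win]
        yw = yw - yw.mean()
        Y = np.fft.fft2(yw)
        for b, mask in enumerate(masks):
            if counts[b] == 0:
                intensity[:, b // 12, b % 12, wi] = 0.0
                continue
            z = np.fft.ifft2(np.where(mask, Y, 0.0))
            intensity[:, b // 12, b % 12, wi] = (np.abs(z) ** 2).mean(axis=1) / counts[b]
    return CorticalRepresentation(
        intensity=intensity,
        cell_counts=counts.reshape(7, 12),
        frame_s=frame_s,
        window_s=win * frame_s,
        hop_s=hop * frame_s,
    )


def cortical_representation(
    w: Waveform,
    max_duration_s: float = 30.0,
    frame_s: float = FRAME_S,
    window_s: float = 4.0,
    hop_s: float = 2.0,
) -> CorticalRepresentation:
    """Full pipeline: waveform -> envelope spectrogram -> modulation bins.

    Only the first ``max_duration_s`` seconds are analysed.
    """
    n_max = int(round(max_duration_s * w.sample_rate))
    if w.n_samples > n_max:
        w = Waveform(w.samples[:n_max], w.sample_rate)
    spec = auditory_spectrogram(w, frame_s=frame_s)
    return modulation_energy(spec, frame_s=frame_s, window_s=window_s, hop_s=hop_s)


# ----------------------------------------------------------------------
# Region of interest


@dataclass(frozen=True)
class RoiSpec:
    """Frequency x temporal-modulation region previously linked to
    unpleasantness: 2500-5500 Hz, 1-16 Hz modulation magnitude; intensity is
    averaged over time and all spectral-modulation scales."""

    freq_lo: float = 2500.0
    freq_hi: float = 5500.0
    tmod_lo: float = 1.0
    tmod_hi: float = 16.0

    def __post_init__(self):
        if not (self.freq_lo < self.freq_hi and self.tmod_lo < self.tmod_hi):
            raise ValueError("ROI bounds must satisfy lo < hi on both axes")


def roi_energy(rep: CorticalRepresentation, roi: RoiSpec | None = None) -> float:
    """Mean intensity inside the ROI (over channels, scales, rates, time)."""
    roi = roi or RoiSpec()
    fc = rep.channel_centres_hz
    ch = (fc >= roi.freq_lo) & (fc <= roi.freq_hi)
    if not ch.any():
        raise ValueError(
            f"no filterbank channels inside [{roi.freq_lo}, {roi.freq_hi}] Hz"
        )
    mag = np.abs(rep.temporal_mod_bins)
    rt = (mag >= roi.tmod_lo) & (mag <= roi.tmod_hi)
    return float(rep.intensity[ch][:, :, rt, :].mean())


# ----------------------------------------------------------------------
# Spearman correlation with exact / approximate critical values


@lru_cache(maxsize=32)
def _exact_rho_tail(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Attainable rho values (descending) and their tail probabilities
    P(rho >= value) under uniform random permutation of untied ranks."""
    fact = factorial(n)
    perms = np.fromiter(
        chain.from_iterable(permutations(range(n))), dtype=np.int8, count=fact * n
    ).reshape(fact, n)
    ref = np.arange(n, dtype=np.int16)
    d2 = np.empty(fact, dtype=np.int32)
    step = 200_000
    for lo in range(0, fact, step):
        diff = perms[lo : lo + step].astype(np.int16) - ref
        d2[lo : lo + len(diff)] = (diff.astype(np.int32) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    values, counts = np.unique(rho, return_counts=True)
    values, counts = values[::-1], counts[::-1]  # descending
    tail = np.cumsum(counts) / fact
    return values, tail


def spearman_critical_value(n: int, alpha: float = 0.05, method: str = "t_approx") -> float:
    """One-tailed critical value for Spearman's rho at significance alpha.

    ``method="exact"`` enumerates all n! rank permutations (n <= 10) and
    returns the smallest attainable rho c with P(rho >= c) <= alpha;
    ``method="t_approx"`` uses c = t / sqrt(df + t^2) with df = n - 2 and t
    the one-tailed Student quantile.  Two-tailed values follow by calling
    with alpha/2.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method == "exact":
        if n > 10:
            raise ValueError(
                f"exact enumeration infeasible for n = {n} (> 10); use "
                "method='t_approx' or Monte Carlo"
            )
        values, tail = _exact_rho_tail(n)
        ok = values[tail <= alpha]
        if ok.size == 0:
            raise ValueError(f"alpha = {alpha} unattainable for n = {n}")
        return float(ok[-1])
    if method == "t_approx":
        df = n - 2
        t = stats.t.ppf(1.0 - alpha, df)
        return float(t / np.sqrt(df + t * t))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class RoiCorrelation:
    """Spearman correlation between per-sound ROI energy and mean ratings."""

    rho: float
    n: int
    critical_value: float
    significant: bool
    method: str


def correlate_roi_ratings(
    roi_values: np.ndarray,
    mean_ratings: np.ndarray,
    alpha: float = 0.05,
    method: str = "auto",
) -> RoiCorrelation:
    """Spearman rho (average-rank ties) with a one-tailed significance flag.

    ``method="auto"`` uses exact enumeration for n <= 10 and the t
    approximation above.  A constant input vector leaves rho undefined
    (NaN, flagged not significant).
    """
    x = np.asarray(roi_values, dtype=float)
    y = np.asarray(mean_ratings, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("roi_values and mean_ratings must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 sounds")
    if method == "auto":
        method = "exact" if n <= 10 else "t_approx"
    crit = spearman_critical_value(n, alpha, method=method)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined")
        return RoiCorrelation(float("nan"), n, crit, False, method)
    rho = float(stats.spearmanr(x, y).statistic)
    return RoiCorrelation(rho, n, crit, bool(rho >= crit), method)
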
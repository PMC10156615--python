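"""Time-domain sound scrambling.

Short snippets (default 15 ms) are locally re-ordered, each moving no more
than a bounded distance (default 400 ms) from its original position.  This
destroys local temporal structure -- rendering a sound unrecognisable --
while the long-term spectral content is preserved.  The permutation comes
from sorting snippet indices keyed by index + uniform jitter scaled to the
window, which bounds the displacement by construction; joins are smoothed
with short raised-cosine crossfades (amplitude-complementary, so an identity
permutation reconstructs the input exactly away from the signal edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import Waveform

__all__ = ["ScrambleSpec", "scramble_waveform", "scramble_report", "ScrambleReport"]


@dataclass(frozen=True)
class ScrambleSpec:
    """Scrambling parameters: snippet length, displacement window, crossfade."""

    snippet_s: float = 0.015
    window_s: float = 0.400
    crossfade_s: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.snippet_s <= self.window_s:
            raise ValueError("require 0 < snippet_s <= window_s")
        if not 0 <= self.crossfade_s < self.snippet_s / 2:
            raise ValueError("crossfade_s must be shorter than half a snippet")


def _bounded_permutation(n_snippets: int, window_snippets: float, rng) -> np.ndarray:
    """Permutation with |new - old| < window_snippets, via jittered sort."""
    keys = np.arange(n_snippets) + rng.uniform(0.0, window_snippets, n_snippets)
    return np.argsort(keys, kind="stable")


def scramble_waveform(w: Waveform, spec: ScrambleSpec | None = None) -> Waveform:
    """Scramble a waveform; output has the same duration and sample rate.

    Raises if the input is empty or shorter than the displacement window.
    The displacement bound is asserted on every run.
    """
    spec = spec or ScrambleSpec()
    if w.n_samples == 0:
        raise ValueError("cannot scramble a zero-length waveform")
    sr = w.sample_rate
    S = max(1, int(round(spec.snippet_s * sr)))
    F = int(round(spec.crossfade_s * sr))
    win_samples = int(round(spec.window_s * sr))
    if w.n_samples < win_samples:
        raise ValueError(
            f"waveform ({w.n_samples} samples) shorter than the scrambling "
            f"window ({win_samples} samples)"
        )
    n = w.n_samples
    K = n // S
    rng = np.random.default_rng(spec.seed)
    perm = _bounded_permutation(K, spec.window_s / spec.snippet_s, rng)

    # Hard invariant: no snippet moves further than the window.
    disp = np.abs(np.arange(K) - perm) * S
    if K and disp.max() > win_samples:  # pragma: no cover - holds by construction
        raise AssertionError("displacement bound violated")

    x = w.samples
    out = np.zeros(n)
    two_f = 2 * F
    if two_f:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(two_f) + 0.5) / two_f))
    else:
        ramp = np.empty(0)

    def overlap_add(src_start: int, tgt_start: int, length: int, head: bool, tail: bool):
        seg = np.zeros(length)
        s_lo, s_hi = max(src_start, 0), min(src_start + length, n)
        if s_hi > s_lo:
            seg[s_lo - src_start : s_hi - src_start] = x[s_lo:s_hi]
        env = np.ones(length)
        if head and two_f:
            env[:two_f] *= ramp
        if tail and two_f:
            env[-two_f:] *= ramp[::-1]
        t_lo, t_hi = max(tgt_start, 0), min(tgt_start + length, n)
        if t_hi > t_lo:
            out[t_lo:t_hi] += (seg * env)[t_lo - tgt_start : t_hi - tgt_start]

    for j in range(K):
        i = int(perm[j])
        overlap_add(i * S - F, j * S - F, S + two_f, head=True, tail=True)
    if K * S < n:  # trailing partial snippet stays in place
        overlap_add(K * S - F, K * S - F, (n - K * S) + F, head=True, tail=False)
    return Waveform(np.clip(out, -1.0, 1.0), sr)


# ----------------------------------------------------------------------
# Similarity report


@dataclass
class ScrambleReport:
    """Spectral and temporal-modulation similarity between two waveforms.

    Scrambling should leave ``band_delta_db`` small (long-term 1/3-octave
    spectrum preserved) while reducing coherent temporal modulation, which
    shows up as a drop in the scrambled rate marginal at the modulation rate
    of the input.
    """

    band_centres_hz: np.ndarray
    band_delta_db: np.ndarray  # scrambled minus original, per occupied band
    spectral_distance_db: float  # max |delta| over occupied bands
    rate_bins_hz: np.ndarray
    rate_marginal_original: np.ndarray
    rate_marginal_scrambled: np.ndarray
    modulation_distance: float  # L1 distance of normalised rate marginals


def third_octave_energies(
    w: Waveform, f_lo: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Long-term energy per 1/3-octave band (centres 1000 * 2^(k/3) Hz)."""
    X = np.abs(np.fft.rfft(w.samples)) ** 2
    f = np.fft.rfftfreq(w.n_samples, 1.0 / w.sample_rate)
    k_lo = int(np.ceil(3 * np.log2(f_lo / 1000.0)))
    k_hi = int(np.floor(3 * np.log2((w.sample_rate / 2) / 1000.0 / 2 ** (1 / 6))))
    centres, energies = [], []
    for k in range(k_lo, k_hi + 1):
        fc = 1000.0 * 2.0 ** (k / 3.0)
        sel = (f >= fc * 2 ** (-1 / 6)) & (f < fc * 2 ** (1 / 6))
        centres.append(fc)
        energies.append(X[sel].sum())
    return np.array(centres), np.array(energies)


def scramble_report(original: Waveform, scrambled: Waveform) -> ScrambleReport:
    """Quantify what scrambling preserved (spectrum) and removed (modulation)."""
    if original.sample_rate != scrambled.sample_rate:
        raise ValueError("sample rates differ")
    if original.n_samples != scrambled.n_samples:
        raise ValueError("durations differ")

    from .psychoacoustics import auditory_spectrogram, modulation_energy

    centres, e_orig = third_octave_energies(original)
    _, e_scr = third_octave_energies(scrambled)
    eps = 1e-12 * max(e_orig.max(), e_scr.max(), 1e-300)
    occupied = (e_orig > eps) | (e_scr > eps)
    delta = np.zeros_like(e_orig)
    delta[occupied] = 10.0 * np.log10(
        (e_scr[occupied] + eps) / (e_orig[occupied] + eps)
    )
    spectral_distance = float(np.abs(delta[occupied]).max()) if occupied.any() else 0.0

    silent = np.abs(original.samples).max() == 0 and np.abs(scrambled.samples).max() == 0
    if silent:
        rate_bins = np.array([])
        m_orig = m_scr = np.array([])
        mod_distance = 0.0
    else:
        rep_o = modulation_energy(auditory_spectrogram(original))
        rep_s = modulation_energy(auditory_spectrogram(scrambled))
        rate_bins = rep_o.temporal_mod_bins
        m_orig = rep_o.rate_marginal()
        m_scr = rep_s.rate_marginal()
        po = m_orig / m_orig.sum() if m_orig.sum() > 0 else m_orig
        ps = m_scr / m_scr.sum() if m_scr.sum() > 0 else m_scr
        mod_distance = float(np.abs(po - ps).sum())

    return ScrambleReport(
        band_centres_hz=centres[occupied],
        band_delta_db=delta[occupied],
        spectral_distance_db=spectral_distance,
        rate_bins_hz=rate_bins,
        rate_marginal_original=m_orig,
        rate_marginal_scrambled=m_scr,
        modulation_distance=mod_distance,
    )
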
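"""Synthetic rating cohorts and audio stimuli.

The statistical pipeline in this package is built around cohorts of
participants who rate a battery of sounds on 17 descriptors (0-100 visual
analogue scale).  This module generates such cohorts with controllable
structure -- per-cell standardised effect sizes between a case and a control
group, within-participant descriptor correlation, bounded (clipped) ratings
and a latent severity gradient among cases -- together with simple audio
stimuli (tones, noises, amplitude-modulated band noises) with known
spectro-temporal modulation content for exercising the audio-side modules.

Ratings are clipped Gaussians: a latent multivariate normal per participant
and sound, shifted for cases by ``effect_d * rating_sd`` scaled by a
severity-dependent factor, then truncated to the 0-100 scale.  Clipping
introduces a documented shrinkage of realised effect sizes when means sit
near the scale bounds; it is measured by the tests, not hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .audio import Waveform
from .dataset import RatingDataset

__all__ = [
    "DESCRIPTORS",
    "SOUND_CATEGORIES",
    "SOUNDS",
    "ProfileSpec",
    "default_profile",
    "null_profile",
    "generate_cohort",
    "generate_stimulus",
]

# The 17 rating descriptors, in canonical order.
DESCRIPTORS: list[str] = [
    "pain",
    "rage",
    "disgust",
    "hairs_on_end",
    "headache",
    "flinching",
    "tingling",
    "soothing",
    "pleasurable",
    "annoyance",
    "nausea",
    "visual_experiences",
    "distress",
    "body_tension",
    "anxiety",
    "discomfort",
    "too_loud",
]

# Descriptors on which controls tend to score higher than cases.
PLEASANT_DESCRIPTORS = ["soothing", "pleasurable", "visual_experiences"]

# The 32-sound battery: 8 sounds in each of four categories.
SOUND_CATEGORIES: dict[str, str] = {
    "apple_crunch": "human-oral-nasal",
    "crunching_chips": "human-oral-nasal",
    "chewing_gum": "human-oral-nasal",
    "lip_smacking": "human-oral-nasal",
    "coughing": "human-oral-nasal",
    "snoring": "human-oral-nasal",
    "breathing": "human-oral-nasal",
    "sniffling": "human-oral-nasal",
    "basketball": "human-action",
    "chopping_vegetables": "human-action",
    "pen_clicking": "human-action",
    "finger_tapping": "human-action",
    "nails_on_chalkboard": "human-action",
    "rusty_swing": "human-action",
    "typing": "human-action",
    "walking_in_heels": "human-action",
    "birds_singing": "non-human",
    "clock_ticking": "non-human",
    "crow_cawing": "non-human",
    "dog_drinking": "non-human",
    "frog_croaking": "non-human",
    "printer": "non-human",
    "rainfall": "non-human",
    "wind_chimes": "non-human",
    "scrambled_apple_crunch": "scrambled",
    "scrambled_breathing": "scrambled",
    "scrambled_coughing": "scrambled",
    "scrambled_sniffling": "scrambled",
    "scrambled_basketball": "scrambled",
    "scrambled_chopping": "scrambled",
    "scrambled_finger_tapping": "scrambled",
    "scrambled_typing": "scrambled",
}

SOUNDS: list[str] = list(SOUND_CATEGORIES)

# Relative strength of the case > control shift per descriptor in the
# default ("trigger-like") profile.  Signs follow the observed direction:
# aversive descriptors positive, the three pleasant descriptors negative.
_DESCRIPTOR_WEIGHT: dict[str, float] = {
    "body_tension": 1.00,
    "rage": 0.95,
    "annoyance": 0.90,
    "anxiety": 0.85,
    "distress": 0.85,
    "discomfort": 0.80,
    "flinching": 0.70,
    "too_loud": 0.65,
    "disgust": 0.60,
    "pain": 0.40,
    "hairs_on_end": 0.30,
    "headache": 0.30,
    "nausea": 0.25,
    "tingling": 0.20,
    "soothing": -0.45,
    "pleasurable": -0.50,
    "visual_experiences": -0.40,
}

# Per-sound overall effect magnitude: well-documented triggers strongest,
# two scrambled sounds carrying no group signal at all.
_SOUND_MAGNITUDE: dict[str, float] = {
    **{s: 1.0 for s in SOUNDS},
    "crunching_chips": 1.20,
    "apple_crunch": 1.15,
    "chewing_gum": 1.05,
    "lip_smacking": 1.00,
    "snoring": 0.95,
    "breathing": 0.90,
    "coughing": 0.85,
    "sniffling": 0.90,
    **{s: 0.70 for s, c in SOUND_CATEGORIES.items() if c == "human-action"},
    **{s: 0.50 for s, c in SOUND_CATEGORIES.items() if c == "non-human"},
    **{s: 0.35 for s, c in SOUND_CATEGORIES.items() if c == "scrambled"},
    "scrambled_breathing": 0.02,
    "scrambled_coughing": 0.02,
}


def identity_scaling(severity: np.ndarray) -> np.ndarray:
    """Default severity scaling: the shift grows linearly with severity."""
    return severity


@dataclass
class ProfileSpec:
    """Population profile from which synthetic cohorts are drawn.

    ``effect_d`` holds the target signed Cohen's d per sound x descriptor
    cell (positive = case group higher).  ``severity_slope`` maps the latent
    per-participant severity in [0, 1] to a multiplier on the case shift; a
    float value means a constant multiplier (so ``severity_slope=1.0``
    applies the full effect to every case).
    """

    sounds: list[str] = field(default_factory=lambda: list(SOUNDS))
    categories: dict[str, str] = field(default_factory=lambda: dict(SOUND_CATEGORIES))
    descriptors: list[str] = field(default_factory=lambda: list(DESCRIPTORS))
    baseline_mean: np.ndarray | None = None
    effect_d: np.ndarray | None = None
    descriptor_corr: np.ndarray | None = None
    rating_sd: float = 18.0
    severity_slope: Callable[[np.ndarray], np.ndarray] | float = identity_scaling
    seed: int = 0

    def __post_init__(self) -> None:
        n_s, n_d = len(self.sounds), len(self.descriptors)
        if self.baseline_mean is None:
            self.baseline_mean = np.full((n_s, n_d), 30.0)
        if self.effect_d is None:
            self.effect_d = np.zeros((n_s, n_d))
        if self.descriptor_corr is None:
            self.descriptor_corr = block_descriptor_corr(self.descriptors)
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.effect_d = np.asarray(self.effect_d, dtype=float)
        self.descriptor_corr = np.asarray(self.descriptor_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_s, n_d = len(self.sounds), len(self.descriptors)
        if self.baseline_mean.shape != (n_s, n_d):
            raise ValueError("baseline_mean must be sounds x descriptors")
        if self.effect_d.shape != (n_s, n_d):
            raise ValueError("effect_d must be sounds x descriptors")
        if self.baseline_mean.min() < 0 or self.baseline_mean.max() > 100:
            raise ValueError("baseline_mean entries must lie in [0, 100]")
        if self.rating_sd <= 0:
            raise ValueError("rating_sd must be positive")
        C = self.descriptor_corr
        if C.shape != (n_d, n_d):
            raise ValueError("descriptor_corr must be descriptors x descriptors")
        if not np.allclose(C, C.T):
            raise ValueError("descriptor_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("descriptor_corr must have unit diagonal")
        lo = np.linalg.eigvalsh(C).min()
        if lo < -1e-10:
            raise ValueError(
                f"descriptor_corr is not positive semi-definite "
                f"(smallest eigenvalue {lo:.3e})"
            )

    def severity_scale(self, severity: np.ndarray) -> np.ndarray:
        if callable(self.severity_slope):
            return np.asarray(self.severity_slope(severity), dtype=float)
        return np.full_like(severity, float(self.severity_slope))

    def cell(self, sound: str, descriptor: str) -> tuple[int, int]:
        return self.sounds.index(sound), self.descriptors.index(descriptor)


def block_descriptor_corr(
    descriptors: list[str],
    rho_within: float = 0.5,
    rho_between: float = -0.3,
    pleasant: list[str] | None = None,
) -> np.ndarray:
    """Two-block compound-symmetry correlation across descriptors.

    Aversive descriptors correlate ``rho_within`` with each other, as do the
    pleasant descriptors; the two blocks correlate ``rho_between``.  The
    exact covariance of real cohorts is unknown, so this is a configurable
    default rather than a constant of the method.
    """
    if pleasant is None:
        pleasant = [d for d in descriptors if d in PLEASANT_DESCRIPTORS]
    sign = np.array([-1.0 if d in pleasant else 1.0 for d in descriptors])
    C = np.where(np.outer(sign, sign) > 0, rho_within, rho_between)
    np.fill_diagonal(C, 1.0)
    lo = np.linalg.eigvalsh(C).min()
    if lo < -1e-10:
        raise ValueError(f"block correlation not PSD (min eigenvalue {lo:.3e})")
    return C


def default_profile(
    effect_scale: float = 1.0,
    seed: int = 0,
    severity_slope: Callable[[np.ndarray], np.ndarray] | float = identity_scaling,
) -> ProfileSpec:
    """The package's reference trigger-profile spec.

    Effects are the outer product of a per-sound magnitude (strongest for
    eating sounds, essentially zero for two of the scrambled sounds) and a
    per-descriptor weight (positive for aversive responses, negative for
    soothing / pleasurable / visual experiences).  Baselines reflect that
    some sounds (nails on chalkboard, rusty swing) are widely disliked
    regardless of group.
    """
    n_s, n_d = len(SOUNDS), len(DESCRIPTORS)
    weights = np.array([_DESCRIPTOR_WEIGHT[d] for d in DESCRIPTORS])
    magnitude = np.array([_SOUND_MAGNITUDE[s] for s in SOUNDS])
    effect = effect_scale * np.outer(magnitude, weights)

    baseline = np.empty((n_s, n_d))
    for i, s in enumerate(SOUNDS):
        for j, d in enumerate(DESCRIPTORS):
            base = 45.0 if d in PLEASANT_DESCRIPTORS else 25.0
            if s in ("nails_on_chalkboard", "rusty_swing") and d not in PLEASANT_DESCRIPTORS:
                base += 20.0  # universally disliked, small group difference
            baseline[i, j] = base

    return ProfileSpec(
        baseline_mean=baseline,
        effect_d=effect,
        severity_slope=severity_slope,
        seed=seed,
    )


def null_profile(seed: int = 0) -> ProfileSpec:
    """A spec with no group signal anywhere (all effect sizes zero)."""
    return ProfileSpec(seed=seed, severity_slope=1.0)


def generate_cohort(
    spec: ProfileSpec,
    n_case: int,
    n_control: int,
    seed: int | None = None,
) -> RatingDataset:
    """Draw a synthetic rating cohort from a :class:`ProfileSpec`.

    Per participant: cases receive a latent severity ~ Uniform(0, 1)
    (controls 0); ratings per sound are a multivariate normal across
    descriptors with correlation ``spec.descriptor_corr`` and SD
    ``spec.rating_sd`` around ``baseline_mean``, shifted for cases by
    ``effect_d * rating_sd * severity_slope(severity)`` and clipped to
    [0, 100].  Deterministic given the seed; participant sub-streams are
    keyed by group and index, so growing the cohort leaves earlier
    participants' data unchanged.

    Trait columns with plausible structure are attached: ``sms_total`` and
    ``trigger_count`` increase with severity for cases, ``aq`` / ``gsq`` /
    ``maia`` / ``asmr15`` are group-independent, ``hyperacusis_flag`` and
    ``pain_factor`` are severity-linked among cases.
    """
    if n_case < 4 or n_control < 4:
        raise ValueError("need at least 4 participants per group")
    spec.validate()
    seed = spec.seed if seed is None else seed

    try:
        L = np.linalg.cholesky(spec.descriptor_corr + 1e-12 * np.eye(len(spec.descriptors)))
    except np.linalg.LinAlgError:  # pragma: no cover - validate() catches first
        raise ValueError("descriptor_corr is not positive semi-definite") from None

    n_s, n_d = len(spec.sounds), len(spec.descriptors)
    n_total = n_case + n_control
    ratings = np.empty((n_total, n_s, n_d))
    severity = np.zeros(n_total)
    group = np.zeros(n_total, dtype=bool)
    group[:n_case] = True

    traits = {
        "sms_total": np.empty(n_total),
        "trigger_count": np.empty(n_total),
        "aq": np.empty(n_total),
        "gsq": np.empty(n_total),
        "maia": np.empty(n_total),
        "asmr15": np.empty(n_total),
        "hyperacusis_flag": np.zeros(n_total),
        "pain_factor": np.empty(n_total),
    }

    for i in range(n_total):
        is_case = i < n_case
        key = (0, i) if is_case else (1, i - n_case)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))
        sev = rng.uniform() if is_case else 0.0
        severity[i] = sev
        shift = spec.effect_d * spec.rating_sd * spec.severity_scale(np.array([sev]))[0]
        z = rng.standard_normal((n_s, n_d)) @ L.T
        x = spec.baseline_mean + spec.rating_sd * z
        if is_case:
            x = x + shift
        ratings[i] = np.clip(x, 0.0, 100.0)

        # Trait scores: severity-linked for cases, background noise otherwise.
        if is_case:
            traits["sms_total"][i] = np.clip(50 + 60 * sev + rng.normal(0, 8), 0, 160)
            traits["trigger_count"][i] = np.clip(round(5 + 20 * sev + rng.normal(0, 3)), 0, 32)
            traits["pain_factor"][i] = np.clip(1 + 3.0 * sev + rng.normal(0, 0.5), 1, 5)
            traits["hyperacusis_flag"][i] = float(sev + rng.normal(0, 0.25) > 0.6)
        else:
            traits["sms_total"][i] = np.clip(rng.normal(9, 9), 0, 160)
            traits["trigger_count"][i] = np.clip(round(rng.normal(1, 1.2)), 0, 32)
            traits["pain_factor"][i] = np.clip(1 + rng.exponential(0.4), 1, 5)
        traits["aq"][i] = float(np.clip(round(rng.normal(17, 8)), 0, 50))
        traits["gsq"][i] = np.clip(rng.normal(45, 18), 0, 150)
        traits["maia"][i] = np.clip(rng.normal(3, 0.8), 0, 5)
        traits["asmr15"][i] = np.clip(rng.normal(2.4, 0.7), 1, 5)

    ids = [f"C{i + 1:04d}" for i in range(n_case)] + [
        f"N{j + 1:04d}" for j in range(n_control)
    ]
    return RatingDataset(
        ratings=ratings,
        sounds=list(spec.sounds),
        descriptors=list(spec.descriptors),
        group=group,
        participant_ids=ids,
        categories=dict(spec.categories),
        traits=pd.DataFrame(traits, index=ids),
        severity=severity,
        provenance="synthetic",
    )


# ----------------------------------------------------------------------
# Audio stimuli


def generate_stimulus(
    kind: str,
    duration_s: float,
    sample_rate: int = 16000,
    carrier_hz: float = 1000.0,
    mod_hz: float = 4.0,
    band: tuple[float, float] | None = None,
    seed: int = 0,
) -> Waveform:
    """Generate a test stimulus with known spectro-temporal content.

    ``kind`` is one of ``"tone"``, ``"noise"``, ``"am-noise"`` (white noise
    with a raised-cosine envelope ``(1 + cos(2 pi f t)) / 2``) or
    ``"band-am"`` (band-limited noise with the same envelope; requires
    ``band=(lo, hi)`` in Hz, and ``mod_hz=0`` disables the modulation).
    The output is peak-normalised to ``|x| <= 1``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)

    if kind == "tone":
        if carrier_hz >= sample_rate / 2:
            raise ValueError(
                f"carrier {carrier_hz} Hz is at or above Nyquist ({sample_rate / 2} Hz)"
            )
        x = np.sin(2 * np.pi * carrier_hz * t)
    elif kind == "noise":
        x = rng.standard_normal(n)
    elif kind in ("am-noise", "band-am"):
        if kind == "band-am":
            if band is None:
                raise ValueError("band-am requires band=(lo, hi)")
            lo, hi = band
            if not 0 <= lo < hi:
                raise ValueError("band must satisfy 0 <= lo < hi")
            if hi > sample_rate / 2:
                raise ValueError(
                    f"band edge {hi} Hz exceeds Nyquist ({sample_rate / 2} Hz)"
                )
            x = _bandpass_noise(n, sample_rate, lo, hi, rng)
        else:
            x = rng.standard_normal(n)
        if mod_hz:
            if mod_hz >= sample_rate / 2:
                raise ValueError("modulation rate above Nyquist")
            x = x * (1.0 + np.cos(2 * np.pi * mod_hz * t)) / 2.0
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")

    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    return Waveform(x, sample_rate)


def _bandpass_noise(n, sample_rate, lo, hi, rng) -> np.ndarray:
    """White noise brick-wall filtered to [lo, hi] Hz in the FFT domain."""
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    X[(f < lo) | (f > hi)] = 0.0
    return np.fft.irfft(X, n)
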
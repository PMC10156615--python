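"""Core in-memory container for multi-descriptor sound-rating cohorts.

A cohort is a dense participants x sounds x descriptors tensor of ratings on
a 0-100 visual-analogue scale, together with a binary diagnostic group label
(case/control), optional trait scores (questionnaire totals, flags) and, for
synthetic cohorts, the latent per-participant severity used to generate the
data.  Every statistical module in the package consumes this one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["RatingDataset"]

RATING_MIN = 0.0
RATING_MAX = 100.0


@dataclass
class RatingDataset:
    """Participants x sounds x descriptors rating tensor with group labels.

    Parameters
    ----------
    ratings:
        Array of shape ``(n_participants, n_sounds, n_descriptors)`` with
        values in ``[0, 100]``.  No missing cells are allowed.
    sounds, descriptors:
        Ordered identifiers for the second and third axes.
    group:
        Boolean per participant; ``True`` marks the case (e.g. misophonic)
        group, ``False`` the control group.
    categories:
        Optional mapping of sound identifier to a category tag
        (``human-oral-nasal``, ``human-action``, ``non-human``, ``scrambled``,
        ``asmr-trigger``).
    traits:
        Per-participant scalar scores (``sms_total``, ``trigger_count``,
        ``aq``, ``asmr15``, ``hyperacusis_flag``, ``pain_factor``, ...),
        indexed like ``participant_ids``.
    severity:
        Latent severity in ``[0, 1]`` (synthetic cohorts only; 0 for
        controls).
    """

    ratings: np.ndarray
    sounds: list[str]
    descriptors: list[str]
    group: np.ndarray
    participant_ids: list[str] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)
    traits: pd.DataFrame | None = None
    severity: np.ndarray | None = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        self.group = np.asarray(self.group, dtype=bool)
        if self.ratings.ndim != 3:
            raise ValueError(
                f"ratings must be 3-D (participants, sounds, descriptors); "
                f"got shape {self.ratings.shape}"
            )
        n, s, d = self.ratings.shape
        if s != len(self.sounds) or d != len(self.descriptors):
            raise ValueError(
                f"ratings shape {self.ratings.shape} inconsistent with "
                f"{len(self.sounds)} sounds / {len(self.descriptors)} descriptors"
            )
        if self.group.shape != (n,):
            raise ValueError("group must have one label per participant")
        if not self.participant_ids:
            self.participant_ids = [f"P{i + 1:04d}" for i in range(n)]
        if len(self.participant_ids) != n:
            raise ValueError("participant_ids length mismatch")
        if not np.all(np.isfinite(self.ratings)):
            raise ValueError("ratings contain non-finite values")
        if self.ratings.size and (
            self.ratings.min() < RATING_MIN or self.ratings.max() > RATING_MAX
        ):
            raise ValueError("ratings outside the [0, 100] rating scale")
        if self.traits is not None and len(self.traits) != n:
            raise ValueError("traits must have one row per participant")

    # ------------------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_sounds(self) -> int:
        return self.ratings.shape[1]

    @property
    def n_descriptors(self) -> int:
        return self.ratings.shape[2]

    @property
    def n_case(self) -> int:
        return int(self.group.sum())

    @property
    def n_control(self) -> int:
        return int((~self.group).sum())

    def sound_index(self, sound: str) -> int:
        try:
            return self.sounds.index(sound)
        except ValueError:
            raise KeyError(f"unknown sound {sound!r}") from None

    def descriptor_index(self, descriptor: str) -> int:
        try:
            return self.descriptors.index(descriptor)
        except ValueError:
            raise KeyError(f"unknown descriptor {descriptor!r}") from None

    # ------------------------------------------------------------------
    def features_for(self, sound: str) -> pd.DataFrame:
        """Participants x descriptors feature block for one sound."""
        idx = self.sound_index(sound)
        return pd.DataFrame(
            self.ratings[:, idx, :],
            index=self.participant_ids,
            columns=self.descriptors,
        )

    def wide(self) -> pd.DataFrame:
        """Widen to the full sounds*descriptors feature matrix.

        Columns are named ``"<sound>:<descriptor>"`` so that a fitted
        aggregate classifier can re-align new cohorts by name.
        """
        cols = [f"{s}:{d}" for s in self.sounds for d in self.descriptors]
        flat = self.ratings.reshape(self.n_participants, -1)
        return pd.DataFrame(flat, index=self.participant_ids, columns=cols)

    def trait(self, name: str) -> np.ndarray:
        if self.traits is None or name not in self.traits.columns:
            raise KeyError(f"trait {name!r} not present in this cohort")
        return self.traits[name].to_numpy(dtype=float)

    # ------------------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "RatingDataset":
        """Restrict to participants selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_participants,):
            raise ValueError("mask must be one boolean per participant")
        return replace(
            self,
            ratings=self.ratings[mask],
            group=self.group[mask],
            participant_ids=[p for p, m in zip(self.participant_ids, mask) if m],
            traits=None if self.traits is None else self.traits.loc[mask],
            severity=None if self.severity is None else self.severity[mask],
        )

    def with_group(self, group: np.ndarray) -> "RatingDataset":
        """Relabel the diagnostic groups (used by cohort splits)."""
        group = np.asarray(group, dtype=bool)
        if group.shape != (self.n_participants,):
            raise ValueError("group must be one label per participant")
        return replace(self, group=group)

    def require_both_groups(self, min_per_group: int = 1) -> None:
        if self.n_case < min_per_group or self.n_control < min_per_group:
            raise ValueError(
                f"need at least {min_per_group} participants per group; "
                f"have {self.n_case} cases / {self.n_control} controls"
            )
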
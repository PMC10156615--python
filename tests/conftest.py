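"""Shared fixtures: cheap forest configs and small synthetic cohorts.

All cohorts are generated programmatically; nothing is loaded from disk.
Forest sizes here are deliberately small -- the checks target statistical
behaviour, not production accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import soundmap as sm
from soundmap.synthetic import DESCRIPTORS


@pytest.fixture(scope="session")
def fast_cfg() -> sm.ForestConfig:
    """Small untuned forest for tests where tuning is not under scrutiny."""
    return sm.ForestConfig(n_trees=50, grid=(4,), min_samples_leaf=5)


@pytest.fixture(scope="session")
def tiny_cfg() -> sm.ForestConfig:
    """Smallest usable forest, for permutation loops."""
    return sm.ForestConfig(n_trees=25, grid=(4,), min_samples_leaf=5)


def make_profile(
    n_sounds: int = 1,
    effect_cells: dict[tuple[int, str], float] | None = None,
    baseline: float = 50.0,
    corr: np.ndarray | None = None,
    severity_slope=1.0,
    seed: int = 0,
    descriptors: list[str] | None = None,
) -> sm.ProfileSpec:
    """Small custom profile: named effect cells on an otherwise null spec."""
    descriptors = descriptors or list(DESCRIPTORS)
    sounds = [f"s{i}" for i in range(n_sounds)]
    eff = np.zeros((n_sounds, len(descriptors)))
    for (i, desc), d in (effect_cells or {}).items():
        eff[i, descriptors.index(desc)] = d
    return sm.ProfileSpec(
        sounds=sounds,
        categories={s: "non-human" for s in sounds},
        descriptors=descriptors,
        baseline_mean=np.full((n_sounds, len(descriptors)), baseline),
        effect_d=eff,
        descriptor_corr=corr if corr is not None else np.eye(len(descriptors)),
        severity_slope=severity_slope,
        seed=seed,
    )


@pytest.fixture(scope="session")
def null_cohort_small() -> sm.RatingDataset:
    """60 + 60 participants, one sound, no group signal anywhere."""
    return sm.generate_cohort(make_profile(seed=11), 60, 60)


@pytest.fixture(scope="session")
def signal_cohort_small() -> sm.RatingDataset:
    """100 + 100 participants, one sound, d = 1.5 on 'rage'."""
    spec = make_profile(effect_cells={(0, "rage"): 1.5}, seed=12)
    return sm.generate_cohort(spec, 100, 100)


def make_manual_dataset(
    ratings: np.ndarray,
    group: np.ndarray,
    sounds: list[str] | None = None,
    descriptors: list[str] | None = None,
    traits: pd.DataFrame | None = None,
) -> sm.RatingDataset:
    """RatingDataset straight from an array (for hand-built examples)."""
    n, s, d = ratings.shape
    return sm.RatingDataset(
        ratings=ratings,
        sounds=sounds or [f"s{i}" for i in range(s)],
        descriptors=descriptors or [f"d{i}" for i in range(d)],
        group=group,
        traits=traits,
    )
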
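"""Random-forest variable selection (thresholding step) and |d| ranking.

Which descriptors drive classification?  For each sound, repeated random
forests yield out-of-bag permutation importances per descriptor; the
data-driven elimination threshold is the minimum prediction of a regression
tree fitted to the importance standard deviations as a function of rank
(the first, "thresholding" step of the VSURF procedure -- the later
interpretation/prediction steps are out of scope).  A census across sounds
counts, per descriptor, how often it is retained; a simple fallback ranking
averages the absolute effect size down each descriptor column of the
effect-size map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeRegressor

from .cartography import EffectSizeMatrix
from .dataset import RatingDataset

__all__ = [
    "ImportanceProfile",
    "oob_permutation_importance",
    "importance_profile",
    "vsurf_threshold",
    "importance_census",
    "mean_abs_effect_ranking",
]


def _bootstrap_indices(tree_random_state: int, n_samples: int) -> np.ndarray:
    """The bootstrap sample drawn by one tree of a scikit-learn forest.

    Mirrors the forest's own sampling (a RandomState seeded with the tree's
    random_state drawing n uniform integers); a test pins this against the
    forest's reported OOB decision function.
    """
    return np.random.RandomState(tree_random_state).randint(0, n_samples, n_samples)


def oob_decision_function(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Out-of-bag case probability per sample (NaN if never out of bag)."""
    n = X.shape[0]
    votes = np.zeros(n)
    counts = np.zeros(n)
    for tree in forest.estimators_:
        oob = np.ones(n, dtype=bool)
        oob[_bootstrap_indices(tree.random_state, n)] = False
        if not oob.any():
            continue
        votes[oob] += tree.predict_proba(X[oob])[:, 1]
        counts[oob] += 1
    with np.errstate(invalid="ignore"):
        return votes / counts


def oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature OOB permutation importance of one fitted forest.

    For each tree: classification error on its out-of-bag samples, minus the
    same error after permuting one feature column among those samples;
    averaged over trees.  Constant features get importance ~0 (not an
    error).
    """
    n, p = X.shape
    y = np.asarray(y)
    vi = np.zeros(p)
    n_used = 0
    for tree in forest.estimators_:
        oob = np.ones(n, dtype=bool)
        oob[_bootstrap_indices(tree.random_state, n)] = False
        idx = np.flatnonzero(oob)
        if idx.size == 0:
            continue
        n_used += 1
        Xo, yo = X[idx], y[idx]
        err0 = float(np.mean(tree.predict(Xo) != yo))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(idx.size), j]
            vi[j] += float(np.mean(tree.predict(Xp) != yo)) - err0
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return vi / n_used


@dataclass
class ImportanceProfile:
    """Mean and SD of permutation importance across repeated forests."""

    descriptors: list[str]
    mean_vi: np.ndarray
    sd_vi: np.ndarray
    n_forests: int
    sound: str = ""

    def ranked(self) -> pd.DataFrame:
        """Descriptors sorted by mean importance, descending."""
        df = pd.DataFrame(
            {"descriptor": self.descriptors, "mean_vi": self.mean_vi, "sd_vi": self.sd_vi}
        )
        return df.sort_values("mean_vi", ascending=False, kind="stable").reset_index(
            drop=True
        )


def importance_profile(
    data: RatingDataset,
    sound: str,
    n_forests: int = 25,
    n_trees: int = 500,
    max_features: int | str = "sqrt",
    seed: int = 0,
) -> ImportanceProfile:
    """Repeated-forest OOB permutation importances for one sound's descriptors."""
    if n_forests < 2:
        raise ValueError("need at least 2 forests to estimate importance SDs")
    X = data.features_for(sound).to_numpy()
    y = data.group.astype(int)
    vis = np.empty((n_forests, X.shape[1]))
    for f in range(n_forests):
        rs = (seed + 104729 * f) % (2**31 - 1)
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features=max_features, random_state=rs
        )
        forest.fit(X, y)
        vis[f] = oob_permutation_importance(
            forest, X, y, np.random.default_rng(rs + 1)
        )
    return ImportanceProfile(
        descriptors=list(data.descriptors),
        mean_vi=vis.mean(axis=0),
        sd_vi=vis.std(axis=0, ddof=1),
        n_forests=n_forests,
        sound=sound,
    )


def vsurf_threshold(
    profile: ImportanceProfile, ccp_fraction: float = 0.01
) -> tuple[list[str], float]:
    """Thresholding step: retain descriptors whose mean importance clears a
    data-driven floor.

    Sort by mean importance descending; fit a piecewise-constant regression
    tree of the importance SD on the rank (cost-complexity penalty
    ``ccp_fraction * var(sd_vi)``, making the rule scale-equivariant); the
    threshold is the minimum predicted SD, and every descriptor with
    ``mean_vi >= threshold`` is retained.  If no importance is positive the
    retained set is empty (with a warning).

    Returns ``(retained_descriptors, threshold)``.
    """
    order = np.argsort(-profile.mean_vi, kind="stable")
    mean_sorted = profile.mean_vi[order]
    sd_sorted = profile.sd_vi[order]
    ranks = np.arange(1, len(order) + 1, dtype=float).reshape(-1, 1)

    tree = DecisionTreeRegressor(
        ccp_alpha=ccp_fraction * float(np.var(sd_sorted)), random_state=0
    )
    tree.fit(ranks, sd_sorted)
    threshold = float(tree.predict(ranks).min())

    if (profile.mean_vi <= 0).all():
        warnings.warn("all importances are non-positive; nothing retained")
        return [], threshold
    retained = [
        profile.descriptors[i] for i in order if profile.mean_vi[i] >= threshold
    ]
    return retained, threshold


def importance_census(retained_sets: dict[str, list[str]], descriptors: list[str]) -> pd.DataFrame:
    """Per-descriptor count of sounds for which it was retained, descending."""
    counts = {d: 0 for d in descriptors}
    for sound, retained in retained_sets.items():
        for d in retained:
            if d not in counts:
                raise KeyError(f"retained descriptor {d!r} (sound {sound!r}) unknown")
            counts[d] += 1
    df = pd.DataFrame(
        {"descriptor": list(counts), "n_sounds_retained": list(counts.values())}
    )
    return df.sort_values(
        ["n_sounds_retained", "descriptor"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def mean_abs_effect_ranking(esm: EffectSizeMatrix) -> pd.DataFrame:
    """Descriptors ranked by mean |d| down each column (sign ignored).

    Undefined (NaN) cells are excluded from the mean.
    """
    mean_abs = esm.d.abs().mean(axis=0, skipna=True)
    df = pd.DataFrame(
        {"descriptor": mean_abs.index, "mean_abs_d": mean_abs.to_numpy()}
    )
    return df.sort_values("mean_abs_d", ascending=False, kind="stable").reset_index(
        drop=True
    )
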
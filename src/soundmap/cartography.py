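"""Effect-size maps: the sounds x descriptors Cohen's d "cartography".

The map is the descriptive backbone of the pipeline: one signed Cohen's d
(case minus control, pooled-SD form) per sound x descriptor cell, with sounds
ordered by classifier AUC and descriptors ordered by hierarchical clustering
of their correlations, so that co-varying response features sit together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataset import RatingDataset

__all__ = [
    "EffectSizeMatrix",
    "cohens_d",
    "effect_size_map",
    "cluster_descriptors",
    "mean_rating_ranks",
    "RankAgreement",
]


def cohens_d(case: np.ndarray, control: np.ndarray) -> float:
    """Pooled-SD (Student) Cohen's d, case minus control.

    d = (mean1 - mean0) / s_p with
    s_p = sqrt(((n1-1) s1^2 + (n0-1) s0^2) / (n1 + n0 - 2)).
    Returns NaN when either group has fewer than two observations or the
    pooled SD is zero.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n0 = case.size, control.size
    if n1 < 2 or n0 < 2:
        return float("nan")
    s1, s0 = case.var(ddof=1), control.var(ddof=1)
    sp2 = ((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2)
    if sp2 <= 0:
        return float("nan")
    return float((case.mean() - control.mean()) / np.sqrt(sp2))


@dataclass
class EffectSizeMatrix:
    """Signed sounds x descriptors Cohen's d map (case > control orientation)."""

    d: pd.DataFrame  # index: sounds, columns: descriptors; NaN = undefined
    n_case: int
    n_control: int
    sound_order: list[str] | None = None
    descriptor_order: list[str] | None = None

    @property
    def sounds(self) -> list[str]:
        return list(self.d.index)

    @property
    def descriptors(self) -> list[str]:
        return list(self.d.columns)

    def ordered(self) -> pd.DataFrame:
        """The map with any sound/descriptor ordering applied."""
        out = self.d
        if self.sound_order is not None:
            out = out.loc[self.sound_order]
        if self.descriptor_order is not None:
            out = out[self.descriptor_order]
        return out

    def to_tsv(self, path) -> None:
        self.ordered().to_csv(path, sep="\t")


def effect_size_map(data: RatingDataset) -> EffectSizeMatrix:
    """Per-cell Cohen's d between the case and control groups."""
    data.require_both_groups()
    case = data.ratings[data.group]
    control = data.ratings[~data.group]
    n_s, n_d = data.n_sounds, data.n_descriptors
    d = np.empty((n_s, n_d))
    for i in range(n_s):
        for j in range(n_d):
            d[i, j] = cohens_d(case[:, i, j], control[:, i, j])
    return EffectSizeMatrix(
        d=pd.DataFrame(d, index=data.sounds, columns=data.descriptors),
        n_case=data.n_case,
        n_control=data.n_control,
    )


def cluster_descriptors(
    data: RatingDataset, level: str = "pooled"
) -> tuple[list[str], np.ndarray]:
    """Order descriptors by average-linkage clustering of 1 - Pearson r.

    ``level="pooled"`` correlates descriptor columns over all participant x
    sound observations; ``level="sound_mean"`` first averages over
    participants per sound.  Constant descriptors get maximal distance (2)
    to everything and therefore cluster last; a warning is emitted.

    Returns ``(leaf_order, linkage_matrix)``.
    """
    if data.n_descriptors < 2:
        raise ValueError("need at least 2 descriptors to cluster")
    if level == "pooled":
        obs = data.ratings.reshape(-1, data.n_descriptors)
    elif level == "sound_mean":
        obs = data.ratings.mean(axis=0)
    else:
        raise ValueError(f"unknown pooling level {level!r}")

    sd = obs.std(axis=0)
    constant = sd == 0
    if constant.any():
        names = [d for d, c in zip(data.descriptors, constant) if c]
        warnings.warn(f"constant descriptor(s) {names}; assigned maximal distance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(obs, rowvar=False)
    dist = 1.0 - r
    dist[np.isnan(dist)] = 2.0  # constant descriptors: maximal distance
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)

    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return [data.descriptors[i] for i in order], Z


@dataclass
class RankAgreement:
    """Cross-group agreement of per-sound mean-rating rankings."""

    descriptor: str
    case_means: pd.Series
    control_means: pd.Series
    case_ranks: pd.Series  # rank 1 = highest mean rating; average-rank ties
    control_ranks: pd.Series
    rho: float
    critical_value: float
    significant: bool


def mean_rating_ranks(
    data: RatingDataset, descriptor: str, alpha: float = 0.05
) -> RankAgreement:
    """Rank sounds by group-mean rating per group; Spearman rho across groups.

    Significance is flagged by comparing rho with the one-tailed Spearman
    critical value at N = number of sounds (t approximation).
    """
    from .psychoacoustics import spearman_critical_value

    j = data.descriptor_index(descriptor)
    case_means = data.ratings[data.group, :, j].mean(axis=0)
    control_means = data.ratings[~data.group, :, j].mean(axis=0)
    # rank 1 = highest mean (most intense); average ranks on ties
    case_ranks = stats.rankdata(-case_means)
    control_ranks = stats.rankdata(-control_means)
    rho = float(stats.spearmanr(case_means, control_means).statistic)
    crit = spearman_critical_value(data.n_sounds, alpha, method="t_approx")
    return RankAgreement(
        descriptor=descriptor,
        case_means=pd.Series(case_means, index=data.sounds),
        control_means=pd.Series(control_means, index=data.sounds),
        case_ranks=pd.Series(case_ranks, index=data.sounds),
        control_ranks=pd.Series(control_ranks, index=data.sounds),
        rho=rho,
        critical_value=crit,
        significant=bool(rho >= crit),
    )
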
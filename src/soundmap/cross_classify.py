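"""Sound-to-sound transfer of diagnostic classifiers.

A classifier trained on the response profile to sound A is applied to the
response profile to sound B (same participants, same 17 descriptors); the
resulting AUC measures how far the diagnostic pattern transfers across
sounds.  A largely significant off-diagonal matrix indicates one common
response profile expressed across many sounds; a near-chance off-diagonal
indicates idiosyncratic, sound-specific profiles.

Off-diagonal transfer follows the train-on-everyone convention: the model
for A is refit on all participants (min-max rescaling fit on A's features
travels with the model, applied to B's features with clipping to [0, 1]).
Because the same participants supply both the training responses (to A) and
the test responses (to B), transfer AUCs share participant-level dependence
with the training data; an optional split-half mode trains on half the
participants' A-responses and tests on the other half's B-responses for an
estimate free of that dependence.  Diagonal cells are the within-sound
cross-validated AUCs and are not transfer estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from dataclasses import replace as _dc_replace

from .classify import (
    ClassifierResult,
    ForestConfig,
    auc_mann_whitney,
    fdr_adjust,
    fit_final_model,
    train_sound_classifier,
)
from .dataset import RatingDataset

__all__ = ["CrossClassMatrix", "cross_classification_matrix"]


@dataclass
class CrossClassMatrix:
    """Sounds x sounds AUC matrix (rows = training sound, cols = test sound)."""

    auc: pd.DataFrame
    p_perm: pd.DataFrame
    q_fdr: pd.DataFrame
    categories: dict[str, str]
    block_summary: pd.DataFrame  # % significant off-diagonal cells per block
    diagonal_results: dict[str, ClassifierResult]
    n_perm: int
    alpha: float
    seed: int

    @property
    def sounds(self) -> list[str]:
        return list(self.auc.index)

    def significant_offdiagonal_fraction(self) -> float:
        """Share of off-diagonal cells significant after FDR."""
        q = self.q_fdr.to_numpy()
        off = ~np.eye(len(q), dtype=bool)
        return float((q[off] < self.alpha).mean())

    def relabelled(self, mapping: dict[str, str]) -> "CrossClassMatrix":
        """Rename sounds; rows and columns move together."""
        return _dc_replace(
            self,
            auc=self.auc.rename(index=mapping, columns=mapping),
            p_perm=self.p_perm.rename(index=mapping, columns=mapping),
            q_fdr=self.q_fdr.rename(index=mapping, columns=mapping),
            categories={mapping.get(s, s): c for s, c in self.categories.items()},
        )


def _transfer_auc_matrix(
    X_by_sound: list[np.ndarray],
    y: np.ndarray,
    cfg: ForestConfig,
    seed: int,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
) -> np.ndarray:
    """AUC[a, b]: model fit on sound a's features, scored on sound b's."""
    n_sounds = len(X_by_sound)
    auc = np.full((n_sounds, n_sounds), np.nan)
    tr = slice(None) if train_idx is None else train_idx
    te = slice(None) if test_idx is None else test_idx
    for a in range(n_sounds):
        model, _ = fit_final_model(X_by_sound[a][tr], y[tr], cfg, seed + a)
        for b in range(n_sounds):
            if b == a:
                continue
            scores = model.predict_proba(X_by_sound[b][te])[:, 1]
            auc[a, b] = auc_mann_whitney(scores, y[te])
    return auc


def cross_classification_matrix(
    data: RatingDataset,
    seed: int = 0,
    n_perm: int = 199,
    alpha: float = 0.05,
    folds: int = 10,
    config: ForestConfig | None = None,
    diagonal_results: dict[str, ClassifierResult] | None = None,
    split_half: bool = False,
) -> CrossClassMatrix:
    """Build the full transfer matrix with permutation + FDR inference.

    Transfer models use min-max rescaling with clipping (the scaler fitted
    on the training sound travels to the test sound).  Permutation nulls
    shuffle the group labels once per permutation and rerun every
    train/test pair, so the joint null respects the shared labels; p-values
    are FDR-adjusted across all off-diagonal cells jointly.  Diagonal cells
    are within-sound CV results (computed here unless supplied).

    The matrix is deliberately not symmetrised; train->test asymmetry is
    part of the result.
    """
    if data.n_sounds < 2:
        raise ValueError("need at least 2 sounds for cross-classification")
    data.require_both_groups()
    cfg = _dc_replace(config or ForestConfig(), clip_rescale=True)
    sounds = data.sounds
    y = data.group
    X_by_sound = [data.ratings[:, i, :] for i in range(data.n_sounds)]

    train_idx = test_idx = None
    if split_half:
        rng = np.random.default_rng(seed)
        half = np.zeros(data.n_participants, dtype=bool)
        for grp in (True, False):
            idx = np.flatnonzero(data.group == grp)
            half[rng.permutation(idx)[: len(idx) // 2]] = True
        train_idx, test_idx = np.flatnonzero(half), np.flatnonzero(~half)

    obs = _transfer_auc_matrix(X_by_sound, y, cfg, seed, train_idx, test_idx)

    # Joint permutation null: one label shuffle per permutation, all cells.
    rng = np.random.default_rng(seed + 1)
    exceed = np.zeros_like(obs)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null = _transfer_auc_matrix(
            X_by_sound, y_perm, cfg, seed + 7919 * (b + 1), train_idx, test_idx
        )
        exceed += (null >= obs).astype(float)
    p = (1.0 + exceed) / (1.0 + n_perm)

    # Diagonal: within-sound cross-validated results.
    if diagonal_results is None:
        diagonal_results = {
            s: train_sound_classifier(data, s, folds=folds, config=cfg, seed=seed + i)
            for i, s in enumerate(sounds)
        }
    for i, s in enumerate(sounds):
        obs[i, i] = diagonal_results[s].auc
        p[i, i] = diagonal_results[s].p_perm if diagonal_results[s].p_perm is not None else np.nan

    # FDR across off-diagonal cells jointly.
    off = ~np.eye(len(sounds), dtype=bool)
    q = np.full_like(p, np.nan)
    q_off, _ = fdr_adjust(p[off], alpha=alpha)
    q[off] = q_off

    auc_df = pd.DataFrame(obs, index=sounds, columns=sounds)
    p_df = pd.DataFrame(p, index=sounds, columns=sounds)
    q_df = pd.DataFrame(q, index=sounds, columns=sounds)

    block_summary = _block_summary(q_df, data.categories, alpha)

    return CrossClassMatrix(
        auc=auc_df,
        p_perm=p_df,
        q_fdr=q_df,
        categories=dict(data.categories),
        block_summary=block_summary,
        diagonal_results=diagonal_results,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
    )


def _block_summary(
    q: pd.DataFrame, categories: dict[str, str], alpha: float
) -> pd.DataFrame:
    """Percent of FDR-significant off-diagonal cells per category pair."""
    sounds = list(q.index)
    cats = sorted({categories.get(s, "uncategorised") for s in sounds})
    rows = []
    for ca in cats:
        for cb in cats:
            cells = [
                q.loc[a, b]
                for a in sounds
                for b in sounds
                if a != b
                and categories.get(a, "uncategorised") == ca
                and categories.get(b, "uncategorised") == cb
            ]
            cells = np.array(cells, dtype=float)
            cells = cells[~np.isnan(cells)]
            rows.append(
                {
                    "train_category": ca,
                    "test_category": cb,
                    "n_cells": len(cells),
                    "pct_significant": 100.0 * float((cells < alpha).mean())
                    if len(cells)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
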
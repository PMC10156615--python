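"""Per-sound diagnostic classification with permutation-null inference.

For each sound, a random forest predicts case/control status from the 17
descriptor ratings under stratified k-fold cross-validation (default 10
folds), with min-max rescaling fit on training folds only and one tuned
hyperparameter: the number of features considered per split, over a 2..8
grid (tuned by nested inner CV by default).  Accuracy is the area under the
ROC curve computed on pooled out-of-fold case probabilities; significance
comes from re-running the whole pipeline on label-shuffled cohorts, and
multiplicity across sounds is handled by Benjamini-Hochberg FDR.

A single aggregate classifier over the widened sounds x descriptors feature
vector (32 x 17 = 544 features in the default battery) is also provided, and
its fitted form can score new cohorts with column alignment by name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from statsmodels.stats.multitest import multipletests

from .dataset import RatingDataset

__all__ = [
    "ClassifierResult",
    "ParticipantScore",
    "ForestConfig",
    "auc_mann_whitney",
    "sensitivity_specificity",
    "train_sound_classifier",
    "permutation_pvalue",
    "permutation_p",
    "fdr_adjust",
    "aggregate_classifier",
    "AggregateModel",
    "participant_counts",
]


# ----------------------------------------------------------------------
# AUC


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the fraction of (case, control) pairs in which the case scores
    higher, counting ties as half.  ``labels`` is boolean (True = case).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def sensitivity_specificity(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    convention: str = "as-reported",
) -> tuple[float, float]:
    """(sensitivity, specificity) of thresholded case probabilities.

    The default ``"as-reported"`` convention follows the source analyses of
    this pipeline, which label the proportion of *cases* correctly classed
    as "specificity" and the proportion of *controls* correctly classed as
    "sensitivity" -- the reverse of standard epidemiological usage.  Pass
    ``convention="standard"`` for the conventional orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    case_correct = float((scores[labels] >= threshold).mean())
    control_correct = float((scores[~labels] < threshold).mean())
    if convention == "as-reported":
        return control_correct, case_correct
    if convention == "standard":
        return case_correct, control_correct
    raise ValueError(f"unknown convention {convention!r}")


# ----------------------------------------------------------------------
# Forest pipeline


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the forest pipeline.

    ``grid`` is the candidate set for ``max_features`` (features considered
    per split); a single-element grid disables tuning.  ``inner_folds``
    controls the nested CV used for tuning inside each training fold
    (``tune="across"`` instead picks one value on the full data -- cheaper
    and closer to un-nested tuning).
    """

    n_trees: int = 500
    grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    inner_folds: int = 3
    tune: str = "nested"
    clip_rescale: bool = False
    min_samples_leaf: int = 10

    def __post_init__(self):
        if self.tune not in ("nested", "across"):
            raise ValueError("tune must be 'nested' or 'across'")
        if not self.grid:
            raise ValueError("grid must be non-empty")


def _make_pipeline(max_features: int, cfg: "ForestConfig", random_state: int) -> Pipeline:
    # min_samples_leaf > 1 smooths leaf probabilities, which stabilises the
    # pooled out-of-fold AUC relative to fully-grown trees.
    return Pipeline(
        [
            ("rescale", MinMaxScaler(clip=cfg.clip_rescale)),
            (
                "forest",
                RandomForestClassifier(
                    n_estimators=cfg.n_trees,
                    max_features=max_features,
                    min_samples_leaf=cfg.min_samples_leaf,
                    random_state=random_state,
                ),
            ),
        ]
    )


def _tune_max_features(X, y, cfg: ForestConfig, rs: int) -> int:
    """Pick max_features by inner stratified CV AUC (ties -> smallest)."""
    grid = [m for m in cfg.grid if m <= X.shape[1]] or [X.shape[1]]
    if len(grid) == 1:
        return grid[0]
    inner = StratifiedKFold(cfg.inner_folds, shuffle=True, random_state=rs)
    best_m, best_auc = grid[0], -np.inf
    for m in grid:
        oof = np.empty(len(y))
        for k, (tr, te) in enumerate(inner.split(X, y)):
            pipe = _make_pipeline(m, cfg, rs + 17 * k + m)
            pipe.fit(X[tr], y[tr])
            oof[te] = pipe.predict_proba(X[te])[:, 1]
        a = auc_mann_whitney(oof, y)
        if a > best_auc + 1e-12:
            best_m, best_auc = m, a
    return best_m


def fit_final_model(
    X: np.ndarray, y: np.ndarray, cfg: ForestConfig, seed: int
) -> tuple[Pipeline, int]:
    """Tune on the full data and fit one pipeline on all participants."""
    rs = int(seed) % (2**31 - 1)
    m = _tune_max_features(X, y, cfg, rs)
    pipe = _make_pipeline(m, cfg, rs)
    pipe.fit(X, y)
    return pipe, m


def cv_oof_scores(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    cfg: ForestConfig,
    seed: int,
) -> tuple[np.ndarray, list[int]]:
    """Pooled out-of-fold case probabilities from stratified k-fold CV.

    Min-max rescaling and (optionally nested) hyperparameter tuning happen
    inside each training fold, so no information leaks from held-out
    participants.  Returns the out-of-fold scores and the per-fold chosen
    ``max_features``.
    """
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if min(n1, n0) < folds:
        raise ValueError(
            f"only {min(n1, n0)} participants in the smaller group for "
            f"{folds}-fold CV; reduce the number of folds (e.g. folds=5)"
        )
    rs = int(seed) % (2**31 - 1)
    outer = StratifiedKFold(folds, shuffle=True, random_state=rs)
    oof = np.empty(len(y))
    chosen: list[int] = []
    m_across = None
    if cfg.tune == "across":
        m_across = _tune_max_features(X, y, cfg, rs)
    for k, (tr, te) in enumerate(outer.split(X, y)):
        m = m_across if m_across is not None else _tune_max_features(
            X[tr], y[tr], cfg, rs + 1000 * (k + 1)
        )
        pipe = _make_pipeline(m, cfg, rs + k)
        pipe.fit(X[tr], y[tr])
        oof[te] = pipe.predict_proba(X[te])[:, 1]
        chosen.append(m)
    return oof, chosen


# ----------------------------------------------------------------------
# Results


@dataclass
class ClassifierResult:
    """Cross-validated classification result for one sound (or the aggregate)."""

    sound: str
    auc: float
    sensitivity: float
    specificity: float
    oof_scores: np.ndarray
    correct_flags: np.ndarray
    participant_ids: list[str]
    labels: np.ndarray
    tuning: list[int] = field(default_factory=list)
    cv_folds: int = 10
    seed: int = 0
    p_perm: float | None = None
    q_fdr: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc outside [0, 1]")
        if len(self.oof_scores) != len(self.participant_ids):
            raise ValueError("one out-of-fold score per participant required")


@dataclass
class ParticipantScore:
    """Number of sounds for which a case participant was correctly classified."""

    participant_id: str
    n_correct: int
    n_sounds: int

    def __post_init__(self):
        if not 0 <= self.n_correct <= self.n_sounds:
            raise ValueError("n_correct outside [0, n_sounds]")


def train_sound_classifier(
    data: RatingDataset,
    sound: str,
    folds: int = 10,
    config: ForestConfig | None = None,
    seed: int = 0,
    convention: str = "as-reported",
) -> ClassifierResult:
    """Cross-validated per-sound classifier; AUC on pooled out-of-fold scores."""
    cfg = config or ForestConfig()
    X = data.features_for(sound).to_numpy()
    y = data.group
    oof, chosen = cv_oof_scores(X, y, folds, cfg, seed)
    auc = auc_mann_whitney(oof, y)
    sens, spec = sensitivity_specificity(oof, y, convention=convention)
    correct = np.where(y, oof >= 0.5, oof < 0.5)
    return ClassifierResult(
        sound=sound,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        oof_scores=oof,
        correct_flags=correct,
        participant_ids=list(data.participant_ids),
        labels=y.copy(),
        tuning=chosen,
        cv_folds=folds,
        seed=seed,
    )


# ----------------------------------------------------------------------
# Permutation inference


def permutation_pvalue(
    statistic: Callable[[np.ndarray], float],
    labels: np.ndarray,
    n_perm: int,
    seed: int = 0,
    observed: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Generic one-sided permutation p-value for a label statistic.

    ``statistic`` maps a label vector to a scalar; it is evaluated on the
    observed labels and on ``n_perm`` uniform shuffles, and
    ``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    obs = float(statistic(labels)) if observed is None else float(observed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic(rng.permutation(labels))
    p = (1.0 + np.count_nonzero(null >= obs)) / (1.0 + n_perm)
    return float(p), obs, null


def permutation_p(
    data: RatingDataset,
    sound: str,
    n_perm: int = 1000,
    folds: int = 10,
    config: ForestConfig | None = None,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for a per-sound classifier AUC.

    Each shuffle reruns the entire pipeline (rescaling, tuning, CV), so the
    null distribution reflects every data-dependent choice the observed
    statistic made.  Returns ``(p, observed_auc, null_aucs)``.
    """
    cfg = config or ForestConfig()
    X = data.features_for(sound).to_numpy()

    def stat(y: np.ndarray) -> float:
        oof, _ = cv_oof_scores(X, y.astype(bool), folds, cfg, seed)
        return auc_mann_whitney(oof, y.astype(bool))

    return permutation_pvalue(stat, data.group, n_perm, seed=seed + 1)


def fdr_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, rejection_mask)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


# ----------------------------------------------------------------------
# Aggregate classifier


@dataclass
class AggregateModel:
    """Fitted aggregate classifier that can score new cohorts by column name."""

    pipeline: Pipeline
    columns: list[str]
    max_features: int
    seed: int

    def score(self, data: RatingDataset) -> np.ndarray:
        """Case probability per participant of a (possibly new) cohort."""
        wide = data.wide()
        missing = [c for c in self.columns if c not in wide.columns]
        if missing:
            raise ValueError(
                f"cohort lacks {len(missing)} feature column(s) required by the "
                f"model, e.g. {missing[:5]}"
            )
        return self.pipeline.predict_proba(wide[self.columns].to_numpy())[:, 1]

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "AggregateModel":
        import joblib

        return joblib.load(path)


def aggregate_classifier(
    data: RatingDataset,
    folds: int = 10,
    config: ForestConfig | None = None,
    seed: int = 0,
    convention: str = "as-reported",
) -> tuple[ClassifierResult, AggregateModel]:
    """Single classifier over the widened sounds x descriptors pattern.

    Returns the cross-validated result plus a final model refit on all
    participants for scoring new cohorts.
    """
    cfg = config or ForestConfig()
    wide = data.wide()
    X = wide.to_numpy()
    y = data.group
    oof, chosen = cv_oof_scores(X, y, folds, cfg, seed)
    auc = auc_mann_whitney(oof, y)
    sens, spec = sensitivity_specificity(oof, y, convention=convention)
    result = ClassifierResult(
        sound="aggregate",
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        oof_scores=oof,
        correct_flags=np.where(y, oof >= 0.5, oof < 0.5),
        participant_ids=list(data.participant_ids),
        labels=y.copy(),
        tuning=chosen,
        cv_folds=folds,
        seed=seed,
    )
    pipe, m = fit_final_model(X, y, cfg, seed)
    model = AggregateModel(pipeline=pipe, columns=list(wide.columns), max_features=m, seed=seed)
    return result, model


# ----------------------------------------------------------------------
# Per-participant classification counts


def participant_counts(
    results: Iterable[ClassifierResult],
    data: RatingDataset | None = None,
    traits: Sequence[str] = (),
) -> tuple[list[ParticipantScore], pd.DataFrame]:
    """Per-case-participant count of sounds classified correctly.

    Sums ``correct_flags`` across per-sound results for case participants
    (a score from 0 to the number of sounds) and, if trait names are given,
    reports the Pearson correlation of the count with each trait across
    cases.  All results must share the same participant roster.
    """
    results = list(results)
    if not results:
        raise ValueError("no classifier results supplied")
    roster = results[0].participant_ids
    for r in results[1:]:
        if r.participant_ids != roster:
            raise ValueError(
                f"participant roster mismatch between sound {results[0].sound!r} "
                f"and {r.sound!r}"
            )
    labels = results[0].labels
    flags = np.vstack([r.correct_flags for r in results])  # sounds x participants
    counts = flags.sum(axis=0)

    scores = [
        ParticipantScore(pid, int(c), len(results))
        for pid, c, is_case in zip(roster, counts, labels)
        if is_case
    ]

    rows = []
    if traits:
        if data is None:
            raise ValueError("a dataset is required to correlate against traits")
        if list(data.participant_ids) != list(roster):
            raise ValueError("dataset roster does not match classifier results")
        case_counts = counts[labels].astype(float)
        for name in traits:
            if name == "severity":
                if data.severity is None:
                    raise KeyError("cohort has no latent severity")
                vals = data.severity[labels]
            else:
                vals = data.trait(name)[labels]
            if np.std(vals) == 0 or np.std(case_counts) == 0:
                warnings.warn(f"constant values for trait {name!r}; correlation undefined")
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(case_counts, vals)
            rows.append({"trait": name, "r": r, "p": p, "n": len(case_counts)})
    return scores, pd.DataFrame(rows)
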
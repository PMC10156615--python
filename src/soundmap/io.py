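"""Tabular I/O for rating cohorts and result tables, plus run manifests.

Cohorts travel as tidy TSV/CSV: one row per participant x sound, with
participant id, group label and trait columns followed by the 17 descriptor
columns.  The exact column naming of any external deposit is declared in a
:class:`RatingSchema`, not hard-coded.  Result tables are TSV with a small
``# key: value`` metadata header (seed, parameters, software version) so
that every output is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import RatingDataset
from .synthetic import DESCRIPTORS

__all__ = [
    "RatingSchema",
    "read_ratings",
    "write_ratings",
    "write_result_table",
    "read_result_table",
    "config_hash",
    "write_manifest",
]

log = logging.getLogger(__name__)


@dataclass
class RatingSchema:
    """Column naming for tidy rating tables."""

    participant_col: str = "participant_id"
    sound_col: str = "sound"
    group_col: str = "group"
    case_label: str = "case"
    control_label: str = "control"
    category_col: str | None = "category"
    descriptor_cols: list[str] = field(default_factory=lambda: list(DESCRIPTORS))
    trait_cols: list[str] | None = None  # None = autodetect remaining columns

    def reserved(self) -> set[str]:
        cols = {self.participant_col, self.sound_col, self.group_col}
        if self.category_col:
            cols.add(self.category_col)
        return cols


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_ratings(
    path, schema: RatingSchema | None = None, clip: bool = False
) -> RatingDataset:
    """Read a tidy rating table into a :class:`RatingDataset`.

    Every participant must have exactly one row per sound and a value for
    every descriptor column.  Out-of-range ratings raise (naming the
    offending participant/sound/descriptor) unless ``clip=True``.
    """
    schema = schema or RatingSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip float parsing: rating tensors must survive write/read exactly
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")

    missing_cols = [
        c
        for c in [schema.participant_col, schema.sound_col, schema.group_col]
        + schema.descriptor_cols
        if c not in df.columns
    ]
    if missing_cols:
        raise ValueError(f"{path.name}: missing required column(s) {missing_cols}")

    participants = list(dict.fromkeys(df[schema.participant_col]))
    sounds = list(dict.fromkeys(df[schema.sound_col]))
    descriptors = schema.descriptor_cols

    # Completeness: one row per participant x sound.
    counts = df.groupby([schema.participant_col, schema.sound_col]).size()
    expected = {(p, s) for p in participants for s in sounds}
    got = set(counts.index)
    absent = sorted(expected - got)
    if absent:
        raise ValueError(
            f"{path.name}: missing cells for (participant, sound): {absent[:10]}"
            + ("..." if len(absent) > 10 else "")
        )
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"{path.name}: duplicated rows for {list(dups.index)[:10]}")

    # Group labels.
    group_map = {}
    for p, sub in df.groupby(schema.participant_col, sort=False):
        labels = set(sub[schema.group_col])
        if len(labels) > 1:
            raise ValueError(f"participant {p!r} has inconsistent group labels {labels}")
        (label,) = labels
        if label == schema.case_label:
            group_map[p] = True
        elif label == schema.control_label:
            group_map[p] = False
        else:
            raise ValueError(
                f"participant {p!r}: unknown group label {label!r} (expected "
                f"{schema.case_label!r} or {schema.control_label!r})"
            )

    # Tensor assembly.
    p_idx = {p: i for i, p in enumerate(participants)}
    s_idx = {s: i for i, s in enumerate(sounds)}
    ratings = np.empty((len(participants), len(sounds), len(descriptors)))
    vals = df[descriptors].to_numpy(dtype=float)
    rows_p = df[schema.participant_col].map(p_idx).to_numpy()
    rows_s = df[schema.sound_col].map(s_idx).to_numpy()
    ratings[rows_p, rows_s] = vals

    bad = np.argwhere((ratings < 0) | (ratings > 100) | ~np.isfinite(ratings))
    if bad.size:
        if clip and np.all(np.isfinite(ratings)):
            ratings = np.clip(ratings, 0.0, 100.0)
            log.warning("%s: clipped %d out-of-range rating(s)", path.name, len(bad))
        else:
            i, j, k = bad[0]
            raise ValueError(
                f"{path.name}: rating {ratings[i, j, k]!r} out of [0, 100] at "
                f"participant={participants[i]!r} sound={sounds[j]!r} "
                f"descriptor={descriptors[k]!r} ({len(bad)} offending cell(s); "
                "pass clip=True to clip instead)"
            )

    categories = {}
    if schema.category_col and schema.category_col in df.columns:
        categories = dict(
            df.drop_duplicates(schema.sound_col)[
                [schema.sound_col, schema.category_col]
            ].itertuples(index=False)
        )

    trait_cols = schema.trait_cols
    if trait_cols is None:
        trait_cols = [
            c
            for c in df.columns
            if c not in schema.reserved() and c not in descriptors
        ]
    traits = None
    if trait_cols:
        traits = (
            df.drop_duplicates(schema.participant_col)
            .set_index(schema.participant_col)[trait_cols]
            .loc[participants]
        )

    group = np.array([group_map[p] for p in participants])
    return RatingDataset(
        ratings=ratings,
        sounds=sounds,
        descriptors=list(descriptors),
        group=group,
        participant_ids=[str(p) for p in participants],
        categories=categories,
        traits=traits,
        provenance="file",
    )


def write_ratings(data: RatingDataset, path, schema: RatingSchema | None = None) -> None:
    """Write a cohort as a tidy table (inverse of :func:`read_ratings`)."""
    schema = schema or RatingSchema(descriptor_cols=list(data.descriptors))
    path = Path(path)
    rows = []
    for i, pid in enumerate(data.participant_ids):
        base = {
            schema.participant_col: pid,
            schema.group_col: schema.case_label if data.group[i] else schema.control_label,
        }
        if data.traits is not None:
            base.update(data.traits.iloc[i].to_dict())
        for j, sound in enumerate(data.sounds):
            row = dict(base)
            row[schema.sound_col] = sound
            if schema.category_col and data.categories:
                row[schema.category_col] = data.categories.get(sound, "")
            for k, d in enumerate(data.descriptors):
                row[d] = data.ratings[i, j, k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ----------------------------------------------------------------------
# Result tables and manifests


def write_result_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """TSV with a ``# key: value`` header recording provenance."""
    path = Path(path)
    meta = {"soundmap_version": __version__}
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_result_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a result TSV; returns (table, metadata)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# "):
                k, _, v = line[2:].partition(": ")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(run_dir, seed: int, config: dict, outputs: list[str]) -> Path:
    """Write a run manifest (seed, config hash, version, outputs) as JSON."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "soundmap_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": outputs,
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, default=str))
    log.info("run manifest: seed=%s config_hash=%s version=%s",
             seed, manifest["config_hash"], __version__)
    return out
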
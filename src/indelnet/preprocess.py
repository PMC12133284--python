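"""Mutation-level preprocessing of per-residue score tables.

Pipeline: sum the 20 score terms over all residue rows of a mutant, drop the
two internally-constant terms (yhh_planarity, dslf_fa13), discard mutants
whose insertion slots are fewer than ``min_gap`` residues apart, and z-score
normalize each retained term across all retained mutants of the protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    DROPPED_SCORES,
    KEY_COLUMNS,
    RETAINED_SCORES,
    SCORE_NAMES,
    MutantDataset,
    MutantKey,
    PerResidueScoreTable,
)

DEFAULT_MIN_GAP = 12


@dataclass
class NormalizationStats:
    """Per-score mean and population standard deviation over all retained
    mutants of one protein; used to z-score targets and to map predictions
    back to raw Rosetta energy units."""

    mean: pd.Series  # indexed by retained score name
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd must be indexed by the same scores")
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0][0]
            raise ValueError(f"standard deviation must be positive, got sd<=0 for {bad!r}")

    @property
    def scores(self) -> list[str]:
        return list(self.mean.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        payload = json.loads(Path(path).read_text())
        return cls(mean=pd.Series(payload["mean"]), sd=pd.Series(payload["sd"]))


def sum_residue_scores(table: PerResidueScoreTable) -> pd.Series:
    """Collapse a per-residue table to one 20-term score vector by summing
    each term over all residue rows."""
    if len(table.rows) == 0:
        raise ValueError("cannot sum an empty per-residue table")
    values = np.sum(table.rows[list(SCORE_NAMES)].to_numpy(), axis=0)
    return pd.Series(values, index=list(SCORE_NAMES))


def drop_constant_scores(vector: pd.Series) -> pd.Series:
    """Remove the two internally-constant terms from a 20-term vector."""
    if set(vector.index) == set(RETAINED_SCORES):
        raise ValueError("constant scores already dropped (18-term vector)")
    missing = [s for s in SCORE_NAMES if s not in vector.index]
    if missing:
        raise ValueError(f"expected all 20 score terms, missing {missing}")
    return vector.drop(list(DROPPED_SCORES))


def drop_constant_scores_dataset(dataset: MutantDataset) -> MutantDataset:
    """Dataset-level constant-term drop."""
    cols = set(dataset.score_columns)
    if cols == set(RETAINED_SCORES):
        raise ValueError("constant scores already dropped (18-term dataset)")
    if cols != set(SCORE_NAMES):
        raise ValueError("expected all 20 score terms before dropping")
    return MutantDataset(
        scores=dataset.scores.drop(columns=list(DROPPED_SCORES)),
        normalized=dataset.normalized,
        protein=dataset.protein,
    )


def gap_filter(key: MutantKey, min_gap: int = DEFAULT_MIN_GAP) -> bool:
    """Return True when the mutant is retained: insertion slots at least
    ``min_gap`` residues apart (a gap of exactly ``min_gap`` is kept)."""
    return key.gap >= min_gap


def filter_by_gap(dataset: MutantDataset, min_gap: int = DEFAULT_MIN_GAP) -> MutantDataset:
    """Drop mutants whose slots are closer than ``min_gap`` residues."""
    keep = (dataset.scores["p2"] - dataset.scores["p1"]) >= min_gap
    return MutantDataset(
        scores=dataset.scores.loc[keep].reset_index(drop=True),
        normalized=dataset.normalized,
        protein=dataset.protein,
    )


def fit_normalization(dataset: MutantDataset) -> NormalizationStats:
    """Per-score mean and population (divide-by-N) standard deviation over
    all records.  A zero-variance retained score is an error: such a term is
    internally constant and should be excluded the way yhh_planarity and
    dslf_fa13 are."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 records to fit normalization")
    cols = dataset.score_columns
    values = dataset.scores[cols].to_numpy()
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd (ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = cols[zero[0]]
        raise ValueError(
            f"score {bad!r} has zero variance across mutants; it is internally "
            "constant and should be excluded like yhh_planarity/dslf_fa13"
        )
    return NormalizationStats(
        mean=pd.Series(mean, index=cols), sd=pd.Series(sd, index=cols)
    )


def apply_normalization(dataset: MutantDataset, stats: NormalizationStats) -> MutantDataset:
    """z-score every score column: v -> (v - mean) / sd."""
    if dataset.normalized:
        raise ValueError("dataset is already normalized")
    cols = dataset.score_columns
    if set(cols) != set(stats.scores):
        raise ValueError("normalization stats were fitted on a different score set")
    df = dataset.scores.copy()
    df[cols] = (df[cols] - stats.mean[cols]) / stats.sd[cols]
    return MutantDataset(scores=df, normalized=True, protein=dataset.protein)


def invert_normalization(dataset: MutantDataset, stats: NormalizationStats) -> MutantDataset:
    """Map z-scored values back to raw units: v -> v * sd + mean."""
    if not dataset.normalized:
        raise ValueError("dataset is not normalized")
    cols = dataset.score_columns
    df = dataset.scores.copy()
    df[cols] = df[cols] * stats.sd[cols] + stats.mean[cols]
    return MutantDataset(scores=df, normalized=False, protein=dataset.protein)


def preprocess_tables(
    tables: list[PerResidueScoreTable],
    min_gap: int = DEFAULT_MIN_GAP,
    normalize: bool = True,
) -> tuple[MutantDataset, NormalizationStats | None]:
    """Full preprocessing of per-residue tables: sum, drop constants, gap
    filter, z-normalize.  Returns the dataset and the fitted stats (None if
    ``normalize`` is False)."""
    records = []
    for t in tables:
        vec = drop_constant_scores(sum_residue_scores(t))
        row = {"p1": t.key.p1, "p2": t.key.p2, "a1": t.key.a1, "a2": t.key.a2}
        row.update(vec.to_dict())
        records.append(row)
    df = pd.DataFrame(records, columns=list(KEY_COLUMNS) + list(RETAINED_SCORES))
    dataset = filter_by_gap(MutantDataset(scores=df), min_gap=min_gap)
    if len(dataset) == 0:
        raise ValueError(f"no mutants survive the gap >= {min_gap} filter")
    if not normalize:
        return dataset, None
    stats = fit_normalization(dataset)
    return apply_normalization(dataset, stats), stats
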
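"""Domain types and tab-separated I/O for double-insertion score data.

A double-insertion mutant is identified by two insertion slots and the two
amino acids inserted there.  An insertion slot ``p`` is the 1-based index of
the wild-type residue *before which* the new residue is inserted, so every
slot maps to exactly one annotated residue and the slot vocabulary size
equals the protein length ``L``.

All tables are TSV with a header row and ``.`` decimals.  Score tables carry
the key columns ``p1 p2 a1 a2`` (plus ``residue_index`` in the per-residue
dialect) followed by the named Rosetta score columns; annotations carry
``index aa ss sasa volume``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The 20 per-residue Rosetta score terms, in canonical Rosetta order.
SCORE_NAMES: tuple[str, ...] = (
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_rep", "fa_intra_sol",
    "lk_ball_wtd", "fa_elec", "pro_close", "hbond_sr_bb", "hbond_lr_bb",
    "hbond_bb_sc", "hbond_sc", "omega", "fa_dun", "p_aa_pp", "ref",
    "rama_prepro", "total", "yhh_planarity", "dslf_fa13",
)

#: Terms that are internally constant for all mutants of a protein and are
#: discarded before modelling: the tyrosine-hydroxyl planarity torsion and the
#: disulfide geometry potential.
DROPPED_SCORES: tuple[str, ...] = ("yhh_planarity", "dslf_fa13")

#: The 18 retained terms, registry order.
RETAINED_SCORES: tuple[str, ...] = tuple(
    s for s in SCORE_NAMES if s not in DROPPED_SCORES
)

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

KEY_COLUMNS: tuple[str, ...] = ("p1", "p2", "a1", "a2")

VALID_SS = frozenset("HEC")


class FormatError(ValueError):
    """A table does not match the expected column contract."""


@dataclass(frozen=True, order=True)
class MutantKey:
    """Two insertion slots and the amino acids inserted at them.

    Canonicalized so ``p1 < p2``; constructing with ``p1 > p2`` swaps the
    positions together with their residues.  ``a1`` is the residue inserted
    at the smaller position.
    """

    p1: int
    p2: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        p1, p2, a1, a2 = int(self.p1), int(self.p2), self.a1, self.a2
        if p1 == p2:
            raise ValueError(f"insertion slots must differ, got p1=p2={p1}")
        if p1 > p2:
            p1, p2, a1, a2 = p2, p1, a2, a1
        if p1 < 1:
            raise ValueError(f"insertion slot must be >= 1, got {p1}")
        for a in (a1, a2):
            if a not in AMINO_ACIDS:
                raise ValueError(f"unknown amino acid {a!r}")
        object.__setattr__(self, "p1", p1)
        object.__setattr__(self, "p2", p2)
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)

    @property
    def position_pair(self) -> tuple[int, int]:
        return (self.p1, self.p2)

    @property
    def residue_pair(self) -> tuple[str, str]:
        """Ordered residue pair: (residue at smaller slot, at larger slot)."""
        return (self.a1, self.a2)

    @property
    def gap(self) -> int:
        return self.p2 - self.p1


@dataclass
class ProteinAnnotation:
    """Wild-type per-residue annotation: amino acid, secondary structure
    (H=helix, E=sheet, C=neither), solvent-accessible surface area (A^2) and
    residue volume (A^3)."""

    protein_id: str
    residues: pd.DataFrame  # index 1..L, columns aa ss sasa volume

    def __post_init__(self) -> None:
        df = self.residues
        required = ["aa", "ss", "sasa", "volume"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        idx = np.asarray(df.index)
        if len(idx) == 0:
            raise ValueError("annotation has no residues")
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(
                "residue indices must be contiguous 1..L, got "
                f"{idx.min()}..{idx.max()} with {len(idx)} rows"
            )
        bad_ss = set(df["ss"]) - VALID_SS
        if bad_ss:
            raise ValueError(f"secondary-structure labels must be H/E/C, got {sorted(bad_ss)}")
        if (df["sasa"] < 0).any():
            bad = df.index[df["sasa"] < 0][0]
            raise ValueError(f"negative SASA at residue {bad}")
        if (df["volume"] <= 0).any():
            bad = df.index[df["volume"] <= 0][0]
            raise ValueError(f"non-positive volume at residue {bad}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def sasa_ratio(self) -> pd.Series:
        """Per-residue SASA as a fraction of residue volume."""
        return self.residues["sasa"] / self.residues["volume"]


@dataclass
class PerResidueScoreTable:
    """All 20 score terms for every residue row of one mutant structure.

    Row indexing after insertion (original vs mutant numbering) is treated as
    opaque: only the per-column sums are consumed downstream.
    """

    key: MutantKey
    rows: pd.DataFrame  # columns = SCORE_NAMES, one row per residue

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_NAMES if c not in self.rows.columns]
        if missing:
            raise FormatError(f"per-residue table missing score columns: {missing}")
        if len(self.rows) < 1:
            raise ValueError("per-residue table must have at least one row")


@dataclass
class MutantDataset:
    """Mutation-level score records for one protein.

    ``scores`` holds one row per mutant with key columns ``p1 p2 a1 a2``
    followed by named score columns (all 20 terms before the constant-term
    drop, the 18 retained terms after).
    """

    scores: pd.DataFrame
    normalized: bool = False
    protein: ProteinAnnotation | None = None

    def __post_init__(self) -> None:
        for c in KEY_COLUMNS:
            if c not in self.scores.columns:
                raise FormatError(f"dataset missing key column {c!r}")
        if self.scores.duplicated(subset=list(KEY_COLUMNS)).any():
            raise ValueError("duplicate mutant keys in dataset")

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.scores.columns if c not in KEY_COLUMNS]

    def __len__(self) -> int:
        return len(self.scores)

    def keys(self) -> list[MutantKey]:
        return [
            MutantKey(int(r.p1), int(r.p2), r.a1, r.a2)
            for r in self.scores[list(KEY_COLUMNS)].itertuples(index=False)
        ]

    def key_frame(self) -> pd.DataFrame:
        return self.scores[list(KEY_COLUMNS)].copy()


def _check_score_columns(columns: list[str], extra_ok: tuple[str, ...]) -> list[str]:
    """Validate a score-table header; return the score columns present.

    Accepts either the full 20-name set or the 18-name retained set.
    """
    present = [c for c in columns if c not in KEY_COLUMNS and c not in extra_ok]
    unknown = [c for c in present if c not in SCORE_NAMES]
    if unknown:
        raise FormatError(f"unknown score columns: {unknown}")
    present_set = set(present)
    if present_set == set(SCORE_NAMES) or present_set == set(RETAINED_SCORES):
        return present
    missing20 = [c for c in SCORE_NAMES if c not in present_set]
    missing18 = [c for c in RETAINED_SCORES if c not in present_set]
    missing = missing18 if len(missing18) < len(missing20) else missing20
    raise FormatError(f"score table missing columns: {missing}")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", float_precision="round_trip",
            dtype={"a1": str, "a2": str, "aa": str, "ss": str},
        )
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_score_table(
    path: str | Path, dialect: str = "per_mutant"
) -> MutantDataset | list[PerResidueScoreTable]:
    """Read a score TSV.

    ``per_mutant`` returns a :class:`MutantDataset` (one row per mutant);
    ``per_residue`` returns one :class:`PerResidueScoreTable` per mutant,
    grouping rows by key and ordering them by ``residue_index``.
    """
    if dialect not in ("per_mutant", "per_residue"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    for c in KEY_COLUMNS:
        if c not in df.columns:
            raise FormatError(f"score table missing key column {c!r}")
    extra = ("residue_index",) if dialect == "per_residue" else ()
    score_cols = _check_score_columns(list(df.columns), extra)
    for col in score_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based incl. header
            raise FormatError(f"non-numeric value in column {col!r} at line {row}")
        df[col] = vals.astype(float)
    if dialect == "per_mutant":
        return MutantDataset(scores=df[list(KEY_COLUMNS) + score_cols].copy())
    if "residue_index" not in df.columns:
        raise FormatError("per_residue table missing column 'residue_index'")
    tables = []
    for (p1, p2, a1, a2), grp in df.groupby(list(KEY_COLUMNS), sort=True):
        grp = grp.sort_values("residue_index")
        tables.append(
            PerResidueScoreTable(
                key=MutantKey(int(p1), int(p2), str(a1), str(a2)),
                rows=grp[list(SCORE_NAMES)].reset_index(drop=True),
            )
        )
    return tables


def write_score_table(dataset: MutantDataset, path: str | Path) -> None:
    """Write a per-mutant score TSV: key columns then score columns
    alphabetically, floats at full (round-trip) precision."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    cols = list(KEY_COLUMNS) + sorted(dataset.score_columns)
    dataset.scores[cols].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path, protein_id: str | None = None) -> ProteinAnnotation:
    """Read a wild-type annotation TSV with columns index aa ss sasa volume."""
    df = _read_tsv(path)
    required = ["index", "aa", "ss", "sasa", "volume"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    df = df.set_index("index")
    if protein_id is None:
        protein_id = Path(path).stem
    return ProteinAnnotation(protein_id=protein_id, residues=df[["aa", "ss", "sasa", "volume"]])


def write_annotation(ann: ProteinAnnotation, path: str | Path) -> None:
    ann.residues.reset_index(names="index").to_csv(path, sep="\t", index=False)
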
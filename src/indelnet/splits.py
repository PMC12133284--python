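"""Generalization-probing data splits.

Before the conventional train/validation/Test1 cut, two extra test sets are
carved out: Test2 holds every mutant of a random subset of insertion-position
combinations (so its position pairs appear in no other set), and Test3 holds
mutants of residue combinations unseen in train/validation/Test1 (they may
still occur in Test2).  The remainder is shuffled and cut 80/10/10.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import KEY_COLUMNS, MutantDataset

SPLIT_NAMES = ("train", "val", "test1", "test2", "test3")


@dataclass
class SplitSpec:
    """Parameters of the five-way split.

    ``test2_fraction`` / ``test3_fraction`` are target shares of *all*
    mutants; position (residue) pairs are drawn until the held-out mutants
    reach that share.  ``ratios`` split the remainder into train/val/Test1.
    """

    test2_fraction: float = 0.05
    test3_fraction: float = 0.05
    ratios: tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in (("test2_fraction", self.test2_fraction),
                        ("test3_fraction", self.test3_fraction)):
            if not 0 < f < 1:
                raise ValueError(f"{name} must be in (0,1), got {f}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {self.ratios}")
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be non-negative")


@dataclass
class SplitResult:
    """Five disjoint mutant-key sets covering the dataset.

    Each member is a key DataFrame with columns p1 p2 a1 a2, in deterministic
    order for a given (dataset, spec)."""

    train: pd.DataFrame
    val: pd.DataFrame
    test1: pd.DataFrame
    test2: pd.DataFrame
    test3: pd.DataFrame

    def __getitem__(self, name: str) -> pd.DataFrame:
        if name not in SPLIT_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def sizes(self) -> dict[str, int]:
        return {name: len(self[name]) for name in SPLIT_NAMES}

    def save(self, out_dir: str | Path, spec: SplitSpec | None = None) -> None:
        """Write five key TSVs plus a JSON manifest (spec, sizes, checksums)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        checksums = {}
        for name in SPLIT_NAMES:
            path = out / f"{name}.tsv"
            self[name].to_csv(path, sep="\t", index=False)
            checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = {
            "sizes": self.sizes(),
            "checksums": checksums,
        }
        if spec is not None:
            manifest["spec"] = {
                "test2_fraction": spec.test2_fraction,
                "test3_fraction": spec.test3_fraction,
                "ratios": list(spec.ratios),
                "seed": spec.seed,
            }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, out_dir: str | Path) -> "SplitResult":
        out = Path(out_dir)
        frames = {
            name: pd.read_csv(out / f"{name}.tsv", sep="\t", dtype={"a1": str, "a2": str})
            for name in SPLIT_NAMES
        }
        return cls(**frames)


def _pair_codes(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes for position pairs and ordered residue pairs."""
    pos = df["p1"].to_numpy() * 100000 + df["p2"].to_numpy()
    res = np.array([ord(a) for a in df["a1"]]) * 256 + np.array([ord(a) for a in df["a2"]])
    return pos, res


def make_splits(dataset: MutantDataset, spec: SplitSpec) -> SplitResult:
    """Build the five-way split.

    Seeded RNG stream is consumed in a fixed order: Test2 position pairs,
    then Test3 residue pairs, then the remainder shuffle."""
    keys = dataset.key_frame().reset_index(drop=True)
    n_total = len(keys)
    if n_total == 0:
        raise ValueError("empty dataset")
    pos_codes, res_codes = _pair_codes(keys)
    if len(np.unique(pos_codes)) < 3 or len(np.unique(res_codes)) < 3:
        raise ValueError("need at least 3 distinct position pairs and residue pairs")
    rng = np.random.default_rng(spec.seed)

    # --- Test2: hold out whole position-pair combinations -----------------
    uniq_pos, counts_pos = np.unique(pos_codes, return_counts=True)
    order = rng.permutation(len(uniq_pos))
    cum = np.cumsum(counts_pos[order])
    target2 = spec.test2_fraction * n_total
    n_pairs2 = int(np.searchsorted(cum, target2) + 1)
    held_pos = set(uniq_pos[order[:n_pairs2]].tolist())
    in_test2 = np.array([c in held_pos for c in pos_codes])

    remainder = keys.loc[~in_test2].reset_index(drop=True)
    if len(remainder) == 0:
        raise ValueError("test2 fraction exhausts the dataset")
    _, res_rem = _pair_codes(remainder)

    # --- Test3: hold out residue combinations from the remainder ----------
    uniq_res, counts_res = np.unique(res_rem, return_counts=True)
    order3 = rng.permutation(len(uniq_res))
    cum3 = np.cumsum(counts_res[order3])
    target3 = spec.test3_fraction * n_total
    n_pairs3 = int(np.searchsorted(cum3, target3) + 1)
    if n_pairs3 >= len(uniq_res):
        raise ValueError("test3 fraction exhausts the remainder")
    held_res = set(uniq_res[order3[:n_pairs3]].tolist())
    in_test3 = np.array([c in held_res for c in res_rem])

    rest = remainder.loc[~in_test3].reset_index(drop=True)
    if len(rest) == 0:
        raise ValueError("fractions exhaust the dataset")

    # --- remainder: shuffled 80/10/10, floor for train and val ------------
    perm = rng.permutation(len(rest))
    n_train = int(np.floor(spec.ratios[0] * len(rest)))
    n_val = int(np.floor(spec.ratios[1] * len(rest)))
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]
    idx_test1 = perm[n_train + n_val :]
    if len(idx_train) == 0 or len(idx_val) == 0:
        raise ValueError("remainder too small for the requested ratios")

    return SplitResult(
        train=rest.iloc[idx_train].reset_index(drop=True),
        val=rest.iloc[idx_val].reset_index(drop=True),
        test1=rest.iloc[idx_test1].reset_index(drop=True),
        test2=keys.loc[in_test2].reset_index(drop=True),
        test3=remainder.loc[in_test3].reset_index(drop=True),
    )


def verify_splits(result: SplitResult, dataset: MutantDataset) -> dict[str, int]:
    """Leakage report; all-zero for a valid split.

    Counts: mutants in more than one set (``overlap``), dataset mutants
    missing from all sets (``uncovered``), Test2 mutants whose position pair
    occurs outside Test2 (``position_pair_leaks``), and Test3 mutants whose
    residue pair occurs in train/val/Test1 (``residue_pair_leaks``)."""
    frames = {name: result[name] for name in SPLIT_NAMES}
    tagged = pd.concat(
        [f.assign(_split=name) for name, f in frames.items()], ignore_index=True
    )
    key_cols = list(KEY_COLUMNS)
    dup = tagged.duplicated(subset=key_cols, keep=False)
    overlap = int(tagged.loc[dup, key_cols].drop_duplicates().shape[0])

    all_keys = dataset.key_frame().merge(
        tagged[key_cols].drop_duplicates(), on=key_cols, how="left", indicator=True
    )
    uncovered = int((all_keys["_merge"] == "left_only").sum())

    others = tagged[tagged["_split"] != "test2"]
    other_pos = set(zip(others["p1"], others["p2"]))
    t2 = frames["test2"]
    position_pair_leaks = int(
        sum((p1, p2) in other_pos for p1, p2 in zip(t2["p1"], t2["p2"]))
    )

    core = tagged[tagged["_split"].isin(("train", "val", "test1"))]
    core_res = set(zip(core["a1"], core["a2"]))
    t3 = frames["test3"]
    residue_pair_leaks = int(
        sum((a1, a2) in core_res for a1, a2 in zip(t3["a1"], t3["a2"]))
    )
    return {
        "overlap": overlap,
        "uncovered": uncovered,
        "position_pair_leaks": position_pair_leaks,
        "residue_pair_leaks": residue_pair_leaks,
    }
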
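"""Per-score Pearson evaluation, overall and stratified.

Performance is the Pearson correlation between predicted and target z-scored
energy terms, reported per score for each of the five splits.  Two
stratifications of Test1 probe where predictions are reliable:

* secondary structure — a mutant is a *helix* (resp. *sheet*) case when at
  least one insertion slot lands on an H (resp. E) residue; *neither* when
  both slots land on C residues.  Helix and sheet may overlap; *neither* is
  disjoint from both and the three categories cover all mutants.
* solvent accessibility — each slot's residue is classed low/medium/high by
  its SASA/volume ratio against the protein-wide 33rd/66th percentiles
  (strict inequalities; boundary ties are medium).  A mutant is *low_low*
  when both slots are low, *high_high* when both are high, else *other* —
  a partition.

"Inserted into" a feature means the feature of the residue at the insertion
slot (the residue the new one is inserted before).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import KEY_COLUMNS, MutantDataset, MutantKey, ProteinAnnotation
from .model import ModelState, predict
from .splits import SPLIT_NAMES, SplitResult

SS_STRATA = ("all", "helix", "sheet", "neither")
SASA_STRATA = ("low_low", "high_high", "other")


@dataclass(frozen=True)
class SSCategory:
    helix: bool
    sheet: bool

    @property
    def neither(self) -> bool:
        return not self.helix and not self.sheet


def pearson(x, y) -> float:
    """Product-moment correlation; NaN (with a warning) when either input
    has zero variance, rather than a silent 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D sequences of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input; Pearson r undefined", stacklevel=2)
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def ss_category(key: MutantKey, ann: ProteinAnnotation) -> SSCategory:
    """Secondary-structure flags for one mutant (slot inherits the SS label
    of the residue at the slot)."""
    ss = ann.residues["ss"]
    labels = {ss.loc[key.p1], ss.loc[key.p2]}
    return SSCategory(helix="H" in labels, sheet="E" in labels)


def sasa_percentiles(ann: ProteinAnnotation) -> tuple[float, float]:
    """33rd and 66th percentiles (linear interpolation) of the per-residue
    SASA/volume ratios."""
    if ann.length < 3:
        raise ValueError("need at least 3 residues for percentile cuts")
    ratios = ann.sasa_ratio().to_numpy()
    p33, p66 = np.percentile(ratios, [33, 66])
    return float(p33), float(p66)


def sasa_category(
    key: MutantKey, ann: ProteinAnnotation, cuts: tuple[float, float]
) -> str:
    """low_low / high_high / other, from both slots' SASA/volume ratios."""
    p33, p66 = cuts
    ratios = ann.sasa_ratio()

    def classify(p: int) -> str:
        r = ratios.loc[p]
        if r < p33:
            return "low"
        if r > p66:
            return "high"
        return "medium"

    c1, c2 = classify(key.p1), classify(key.p2)
    if c1 == c2 == "low":
        return "low_low"
    if c1 == c2 == "high":
        return "high_high"
    return "other"


def categorize_keys(keys: pd.DataFrame, ann: ProteinAnnotation) -> pd.DataFrame:
    """Vectorized per-mutant category labels: helix/sheet/neither flags and
    the SASA label."""
    ss = ann.residues["ss"]
    s1 = ss.loc[keys["p1"]].to_numpy()
    s2 = ss.loc[keys["p2"]].to_numpy()
    helix = (s1 == "H") | (s2 == "H")
    sheet = (s1 == "E") | (s2 == "E")
    p33, p66 = sasa_percentiles(ann)
    ratios = ann.sasa_ratio()
    r1 = ratios.loc[keys["p1"]].to_numpy()
    r2 = ratios.loc[keys["p2"]].to_numpy()
    low = lambda r: r < p33
    high = lambda r: r > p66
    sasa = np.where(
        low(r1) & low(r2), "low_low", np.where(high(r1) & high(r2), "high_high", "other")
    )
    return pd.DataFrame(
        {
            "helix": helix,
            "sheet": sheet,
            "neither": ~helix & ~sheet,
            "sasa": sasa,
        },
        index=keys.index,
    )


def _per_score_pearson(
    pred: np.ndarray, target: np.ndarray, score_names, split: str, stratum: str
) -> list[dict]:
    rows = []
    n = len(target)
    for j, name in enumerate(score_names):
        if n < 2:
            warnings.warn(
                f"stratum {stratum!r} of {split!r} has fewer than 2 mutants; "
                "Pearson r omitted",
                stacklevel=2,
            )
            r = float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sx, sy = np.std(pred[:, j]), np.std(target[:, j])
                r = (
                    float("nan")
                    if sx == 0 or sy == 0
                    else float(sps.pearsonr(pred[:, j], target[:, j]).statistic)
                )
        rows.append({"split": split, "stratum": stratum, "score": name, "r": r, "n": n})
    return rows


def evaluate(
    state: ModelState,
    dataset: MutantDataset,
    splits: SplitResult,
    ann: ProteinAnnotation | None = None,
    strata_split: str = "test1",
) -> pd.DataFrame:
    """Long-format evaluation report: one row per (split, stratum, score)
    with Pearson r and stratum size.

    Overall rows (stratum "all") cover all five splits; when an annotation
    is supplied, secondary-structure and SASA strata are evaluated on
    ``strata_split`` (Test1 by default)."""
    if not dataset.normalized:
        raise ValueError("evaluation expects the normalized dataset")
    score_names = list(state.score_names)
    rows: list[dict] = []
    per_split: dict[str, tuple[pd.DataFrame, np.ndarray, np.ndarray]] = {}
    for split in SPLIT_NAMES:
        keys = splits[split]
        if len(keys) == 0:
            continue
        merged = keys.merge(dataset.scores, on=list(KEY_COLUMNS), how="left")
        target = merged[score_names].to_numpy()
        pred = predict(state, keys)
        per_split[split] = (keys, pred, target)
        rows.extend(_per_score_pearson(pred, target, score_names, split, "all"))

    if ann is not None and strata_split in per_split:
        keys, pred, target = per_split[strata_split]
        cats = categorize_keys(keys, ann)
        masks = {
            "helix": cats["helix"].to_numpy(),
            "sheet": cats["sheet"].to_numpy(),
            "neither": cats["neither"].to_numpy(),
            "low_low": (cats["sasa"] == "low_low").to_numpy(),
            "high_high": (cats["sasa"] == "high_high").to_numpy(),
            "other": (cats["sasa"] == "other").to_numpy(),
        }
        for stratum, mask in masks.items():
            rows.extend(
                _per_score_pearson(
                    pred[mask], target[mask], score_names, strata_split, stratum
                )
            )
    return pd.DataFrame(rows, columns=["split", "stratum", "score", "r", "n"])
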
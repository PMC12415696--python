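"""Leakage-free cohort preparation.

Three operations on the tile manifest (a DataFrame with ``patient_id`` and
``label`` per tile row):

- :func:`cap_tiles` — limit every case to at most the cohort's median tile
  count, preventing heavily-tiled patients from dominating training;
- :func:`split_patients` — stratified *patient-level* 60:30:10 split, the
  barrier against data leakage: all tiles of a patient land in exactly one
  of train/validation/test;
- :func:`balance_classes` — equalise class counts inside a set by random
  removal from the larger class (applied to train/validation only; the test
  set stays imbalanced to mimic real-world prevalence).

With an even number of cases the median tile count uses the lower of the
two middle values, since an integer cap is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SET_NAMES = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """patient_id -> set-name mapping plus the ratios and seed that made it."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        bad = set(self.assignment.values()) - set(SET_NAMES)
        if bad:
            raise ValueError(f"unknown set names in assignment: {bad}")

    def to_frame(self, labels: dict[str, int] | None = None) -> pd.DataFrame:
        rows = [
            {"patient_id": pid, "class": (labels or {}).get(pid, ""), "set": s}
            for pid, s in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows, columns=["patient_id", "class", "set"])

    def patients_in(self, set_name: str) -> set[str]:
        return {p for p, s in self.assignment.items() if s == set_name}


def lower_median(counts: list[int]) -> int:
    """Median tile count; for even n, the lower of the two middle values."""
    ordered = sorted(counts)
    return ordered[(len(ordered) - 1) // 2]


def cap_tiles(manifest: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subsample cases above the cohort median tile count down to the median.

    The median is computed over per-case counts of the input, all classes
    pooled.  Cases at or below the median keep all tiles; larger cases are
    subsampled uniformly without replacement.  Row order of retained tiles
    is preserved.
    """
    if manifest.empty:
        raise ValueError("cannot cap an empty cohort")
    counts = manifest.groupby("patient_id", sort=False).size()
    median = lower_median(list(counts))
    rng = np.random.default_rng(seed)
    keep_index: list[np.ndarray] = []
    for pid, group in manifest.groupby("patient_id", sort=False):
        if len(group) > median:
            chosen = rng.choice(len(group), size=median, replace=False)
            keep_index.append(group.index.values[np.sort(chosen)])
        else:
            keep_index.append(group.index.values)
    return manifest.loc[np.concatenate(keep_index)].sort_index()


def _apportion(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` patients over the three sets,
    repaired so no set is empty whenever ``n >= 3``."""
    quotas = [n * r for r in ratios]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    if n >= len(SET_NAMES):
        while 0 in counts:
            counts[counts.index(0)] += 1
            counts[int(np.argmax(counts))] -= 1
    return counts


def split_patients(
    manifest: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified random patient-level split.

    Patients are shuffled within each class stratum and dealt into the
    three sets in ``train``, ``val``, ``test`` order with per-class counts
    from largest-remainder apportionment of the ratios.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    by_patient = manifest.drop_duplicates("patient_id")[["patient_id", "label"]]
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label, group in by_patient.groupby("label", sort=True):
        pids = list(group["patient_id"])
        if len(pids) == 0:
            raise ValueError(f"class {label} has no patients")
        if len(pids) < 3:
            raise ValueError(f"class {label} has fewer than 3 patients; cannot fill three sets")
        order = rng.permutation(len(pids))
        counts = _apportion(len(pids), ratios)
        cursor = 0
        for set_name, k in zip(SET_NAMES, counts):
            for idx in order[cursor : cursor + k]:
                assignment[pids[idx]] = set_name
            cursor += k
    return SplitAssignment(assignment=assignment, ratios=ratios, seed=seed)


def assign_tiles(manifest: pd.DataFrame, split: SplitAssignment) -> pd.DataFrame:
    """Tiles inherit their patient's set; returns the manifest plus a ``set`` column."""
    out = manifest.copy()
    out["set"] = out["patient_id"].map(split.assignment)
    missing = out["set"].isna()
    if missing.any():
        raise ValueError(f"patients missing from split: {sorted(out.loc[missing, 'patient_id'].unique())}")
    return out


def balance_classes(tiles: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Equalise class counts by uniform removal from the larger class."""
    counts = tiles["label"].value_counts()
    if set(counts.index) != {0, 1}:
        raise ValueError(f"both classes must be present; found labels {sorted(counts.index)}")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for label, group in tiles.groupby("label", sort=True):
        if len(group) > target:
            chosen = rng.choice(len(group), size=target, replace=False)
            keep.append(group.index.values[np.sort(chosen)])
        else:
            keep.append(group.index.values)
    return tiles.loc[np.concatenate(keep)].sort_index()
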
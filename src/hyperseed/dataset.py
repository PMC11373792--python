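"""Stratified 7:2:1 train/validation/test splitting.

The per-class arithmetic is the rule that reproduces a 7:2:1 layout
exactly on integer counts: ``train = floor(0.7 n)``, ``val =
round-half-up(0.2 n)``, ``test = n - train - val``. For the seven
variety totals 1085/1085/1099/1085/1064/1120/1078 this yields split
totals 5328/1524/764.

By default augmented variants of one original move as a block between
splits (leakage guard, grouped on the manifest's ``origin`` column);
the ungrouped mode splits rows independently and hits the per-class
counts exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitSpec", "split_counts", "assign_split"]

SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class SplitSpec:
    """Ratios fixed at 7:2:1 with the floor / round-half-up / remainder rule."""

    train_frac: float = 0.7
    val_frac: float = 0.2
    rng_seed: int = 0
    group_by_origin: bool = True  # leakage guard; False = split rows independently

    def __post_init__(self) -> None:
        if not (0 < self.train_frac < 1 and 0 < self.val_frac < 1):
            raise ValueError("fractions must be in (0, 1)")
        if self.train_frac + self.val_frac >= 1:
            raise ValueError("train + val fraction must leave room for test")


def split_counts(n: int, spec: SplitSpec = SplitSpec()) -> tuple[int, int, int]:
    """(train, val, test) counts for one class of ``n`` items.

    train = floor(train_frac * n); val = round-half-up(val_frac * n);
    test = remainder. Parts are non-negative and sum to n for all n >= 0.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    train = math.floor(spec.train_frac * n)
    val = math.floor(spec.val_frac * n + 0.5)
    test = n - train - val
    if test < 0:  # only possible for tiny n with aggressive rounding
        val += test
        test = 0
    return train, val, test


def _grouped_counts(n_groups: int, spec: SplitSpec) -> tuple[int, int, int]:
    return split_counts(n_groups, spec)


def assign_split(manifest: pd.DataFrame, spec: SplitSpec = SplitSpec()) -> pd.DataFrame:
    """Add a ``split`` column: stratified by class, seeded shuffle.

    Grouped mode (default) shuffles provenance groups (column ``origin``;
    falls back to ``path`` when absent) so no original's augmented
    variants straddle splits; per-class sizes are then the group-level
    7:2:1 counts times the group size. Ungrouped mode shuffles rows and
    matches :func:`split_counts` per class exactly.
    """
    if "label" not in manifest.columns:
        raise ValueError("manifest must have a 'label' column")
    manifest = manifest.reset_index(drop=True).copy()
    group_col = "origin" if (spec.group_by_origin and "origin" in manifest.columns) else None
    rng = np.random.default_rng(spec.rng_seed)
    split = pd.Series(index=manifest.index, dtype=object)

    for cls in sorted(manifest["label"].astype(str).unique()):
        cls_idx = manifest.index[manifest["label"].astype(str) == cls]
        if group_col is not None:
            groups = manifest.loc[cls_idx].groupby(group_col, sort=True).groups
            keys = sorted(groups.keys())
            order = rng.permutation(len(keys))
            n_tr, n_va, n_te = _grouped_counts(len(keys), spec)
            if n_te == 0 or n_va == 0:
                warnings.warn(
                    f"class {cls!r} has too few groups for three non-empty splits",
                    stacklevel=2,
                )
            bounds = np.cumsum([n_tr, n_va])
            for pos, gi in enumerate(order):
                name = SPLIT_NAMES[int(np.searchsorted(bounds, pos, side="right"))]
                split.loc[groups[keys[gi]]] = name
        else:
            order = rng.permutation(len(cls_idx))
            n_tr, n_va, n_te = split_counts(len(cls_idx), spec)
            if n_te == 0 or n_va == 0:
                warnings.warn(
                    f"class {cls!r} has too few items for three non-empty splits",
                    stacklevel=2,
                )
            bounds = np.cumsum([n_tr, n_va])
            for pos, ri in enumerate(order):
                name = SPLIT_NAMES[int(np.searchsorted(bounds, pos, side="right"))]
                split.loc[cls_idx[ri]] = name

    manifest["split"] = split
    return manifest
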
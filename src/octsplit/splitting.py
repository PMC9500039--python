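"""Train/test split strategies, repeated-CV fold plans, and overlap audits.

Two strategies for carving a test set out of a pool of volumetric slices:

* **per-image** — sample individual slices uniformly per class, ignoring
  which subject or volume they came from. Slices of one volume routinely
  land on both sides of the split, so subject-level information leaks from
  train to test.
* **per-volume/subject** — sample whole units (subjects or volumes) per
  class until the requested test size is reached, then trim within the
  drawn units. No unit ever straddles the split, so with ``unit='subject'``
  the audit overlap is zero by construction.

Both draw a fixed number of test images per class. ``audit_overlap``
quantifies the leak as the fraction of test images whose subject ID also
occurs in the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import DatasetTable

ROLE_TRAIN = "train"
ROLE_VAL = "validation"
ROLE_TEST = "test"
ROLE_EXCLUDED = "excluded"  # trimmed-away slices of drawn test units


@dataclass
class SplitAssignment:
    """Partition of a dataset's records into train/validation/test roles.

    Every record receives exactly one role. ``excluded`` marks slices of
    drawn test units that were trimmed away to hit the exact per-class test
    count: they may not train (their subject is in the test set) and are
    not tested on either.
    """

    strategy: str
    roles: np.ndarray  # object array over record positions
    seed: int

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=object)
        valid = {ROLE_TRAIN, ROLE_VAL, ROLE_TEST, ROLE_EXCLUDED}
        bad = set(self.roles) - valid
        if bad:
            raise ValueError(f"invalid roles {bad}")

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"record_id": np.arange(len(self.roles)),
                             "role": self.roles, "strategy": self.strategy,
                             "seed": self.seed})


@dataclass
class OverlapReport:
    """Subject-ID overlap between a training and a testing table."""

    n_test: int
    n_overlapping: int
    overlap_fraction: float
    offending_subject_ids: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_test": self.n_test,
                "n_overlapping": self.n_overlapping,
                "overlap_fraction": self.overlap_fraction,
                "offending_subject_ids": self.offending_subject_ids,
            },
            indent=2,
        )

    def summary(self) -> str:
        pct = 100.0 * self.overlap_fraction
        return (f"{self.n_overlapping}/{self.n_test} test images "
                f"({pct:.1f}%) share a subject ID with the training set")


def split_per_image(table: DatasetTable, n_test_per_class: int,
                    seed: int) -> SplitAssignment:
    """Draw ``n_test_per_class`` test slices per class uniformly, ignoring identity.

    The remainder is the train pool. Fails if any class would be left with
    an empty train pool.
    """
    rng = np.random.default_rng(seed)
    roles = np.full(len(table), ROLE_TRAIN, dtype=object)
    labels = table.labels
    for cls in table.class_set:
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) <= n_test_per_class:
            raise ValueError(
                f"class {cls!r} has {len(cls_idx)} images; cannot hold out "
                f"{n_test_per_class} and keep a non-empty train pool"
            )
        chosen = rng.choice(cls_idx, size=n_test_per_class, replace=False)
        roles[chosen] = ROLE_TEST
    return SplitAssignment(strategy="per-image", roles=roles, seed=seed)


def split_per_volume_subject(table: DatasetTable, n_test_per_class: int,
                             unit: str = "subject", seed: int = 0) -> SplitAssignment:
    """Draw whole subjects (or volumes) per class for testing.

    Units are drawn uniformly without replacement until their accumulated
    image count reaches ``n_test_per_class``; the drawn pool is then trimmed
    to exactly ``n_test_per_class`` by uniform subsampling *within* the
    drawn units, so no unit ever appears on both sides.
    """
    if unit not in ("subject", "volume"):
        raise ValueError(f"unit must be 'subject' or 'volume', got {unit!r}")
    unit_col = "subject_id" if unit == "subject" else "volume_id"
    rng = np.random.default_rng(seed)
    roles = np.full(len(table), ROLE_TRAIN, dtype=object)
    meta = table.meta
    for cls in table.class_set:
        cls_mask = meta["class_label"] == cls
        cls_total = int(cls_mask.sum())
        if cls_total <= n_test_per_class:
            raise ValueError(
                f"class {cls!r} has {cls_total} images; cannot hold out "
                f"{n_test_per_class} whole-{unit} images and keep a train pool"
            )
        units = sorted(meta.loc[cls_mask, unit_col].unique())
        order = rng.permutation(len(units))
        drawn_idx = []
        accumulated = 0
        for pos in order:
            u = units[pos]
            u_idx = np.flatnonzero(cls_mask.to_numpy() & (meta[unit_col] == u).to_numpy())
            drawn_idx.append(u_idx)
            accumulated += len(u_idx)
            if accumulated >= n_test_per_class:
                break
        if accumulated < n_test_per_class:
            raise ValueError(f"class {cls!r}: units exhausted before reaching the test size")
        drawn = np.concatenate(drawn_idx)
        if cls_total - len(drawn) == 0:
            raise ValueError(
                f"class {cls!r}: drawn {unit}s consume every image; no train pool left"
            )
        keep = rng.choice(drawn, size=n_test_per_class, replace=False)
        roles[keep] = ROLE_TEST
        # trimmed-away slices belong to drawn (test) units; training on them
        # would reintroduce the leak the strategy exists to prevent
        roles[np.setdiff1d(drawn, keep)] = ROLE_EXCLUDED
    return SplitAssignment(strategy=f"per-{unit}", roles=roles, seed=seed)


def audit_overlap(train: DatasetTable, test: DatasetTable) -> OverlapReport:
    """Fraction of test images whose subject ID also occurs in training."""
    if len(test) == 0:
        raise ValueError("cannot audit an empty test table")
    train_subjects = set(train.subject_ids)
    test_subjects = test.subject_ids
    overlap_mask = np.fromiter((s in train_subjects for s in test_subjects),
                               dtype=bool, count=len(test_subjects))
    n_overlap = int(overlap_mask.sum())
    return OverlapReport(
        n_test=len(test),
        n_overlapping=n_overlap,
        overlap_fraction=n_overlap / len(test),
        offending_subject_ids=sorted(set(test_subjects[overlap_mask])),
    )


@dataclass
class FoldPlan:
    """Repeated k-fold cross-validation plan over a dataset.

    For each repeat a fresh test set is drawn with ``seed = base_seed +
    repeat``; the remaining pool is partitioned into ``folds`` validation
    folds (stratified by class for per-image plans; partitioning subjects
    for per-subject/volume plans). Each (repeat, fold) entry trains on the
    other folds, validates on the held-out fold, and tests on the repeat's
    test set — ``repeats x folds`` model slots in total.
    """

    strategy: str
    repeats: int
    folds: int
    base_seed: int
    entries: list[dict] = field(default_factory=list)
    # each entry: {"repeat": r, "fold": f, "train": idx, "validation": idx, "test": idx}

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for role in (ROLE_TRAIN, ROLE_VAL, ROLE_TEST):
                for rid in e[role]:
                    rows.append({"record_id": int(rid), "repeat": e["repeat"],
                                 "fold": e["fold"], "role": role})
        return pd.DataFrame(rows)


def make_fold_plan(table: DatasetTable, strategy: str, n_test_per_class: int,
                   repeats: int = 10, folds: int = 5, base_seed: int = 0,
                   unit: str = "subject") -> FoldPlan:
    """Build the repeated-CV plan for either split strategy.

    ``strategy`` is ``'per-image'`` or ``'per-volume-subject'``. Determinism:
    the whole plan is a function of (table order, strategy, sizes, base_seed).
    """
    if strategy not in ("per-image", "per-volume-subject"):
        raise ValueError(f"unknown strategy {strategy!r}")
    plan = FoldPlan(strategy=strategy, repeats=repeats, folds=folds, base_seed=base_seed)
    meta = table.meta
    for r in range(repeats):
        seed = base_seed + r
        if strategy == "per-image":
            assignment = split_per_image(table, n_test_per_class, seed=seed)
        else:
            assignment = split_per_volume_subject(table, n_test_per_class,
                                                  unit=unit, seed=seed)
        test_idx = assignment.indices(ROLE_TEST)
        pool_idx = assignment.indices(ROLE_TRAIN)
        rng = np.random.default_rng((seed, 1))
        fold_of = np.full(len(table), -1, dtype=np.int64)
        if strategy == "per-image":
            # stratified by class over images
            pool_labels = table.labels[pool_idx]
            for cls in table.class_set:
                cls_pool = pool_idx[pool_labels == cls]
                cls_pool = rng.permutation(cls_pool)
                for f in range(folds):
                    fold_of[cls_pool[f::folds]] = f
        else:
            # folds partition subjects (balanced subject counts per class)
            pool_meta = meta.iloc[pool_idx]
            for cls in table.class_set:
                subjects = sorted(pool_meta.loc[pool_meta["class_label"] == cls,
                                                "subject_id"].unique())
                subjects = rng.permutation(np.asarray(subjects, dtype=object))
                pool_mask = np.zeros(len(table), dtype=bool)
                pool_mask[pool_idx] = True
                for f in range(folds):
                    fold_subjects = set(subjects[f::folds])
                    mask = meta["subject_id"].isin(fold_subjects).to_numpy() & pool_mask
                    fold_of[np.flatnonzero(mask)] = f
        for f in range(folds):
            val_idx = pool_idx[fold_of[pool_idx] == f]
            train_idx = pool_idx[fold_of[pool_idx] != f]
            if len(val_idx) == 0 or len(train_idx) == 0:
                raise ValueError(
                    f"repeat {r} fold {f}: empty train or validation fold "
                    f"(pool too small for {folds} folds)"
                )
            plan.entries.append({"repeat": r, "fold": f, "train": train_idx,
                                 "validation": val_idx, "test": test_idx})
    return plan


def write_audit_report(report: OverlapReport, path) -> None:
    Path(path).write_text(report.to_json() + "\n")
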
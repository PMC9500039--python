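"""In-memory dataset container for volumetric slice classification data.

A dataset is a flat table of 2D grayscale slices, each carrying the identity
metadata (class, subject, volume, slice index) that split strategies and
overlap audits operate on. Images live in a single ``(n, H, W)`` float32
array in ``[0, 1]``; metadata lives in a parallel :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["class_label", "subject_id", "volume_id", "slice_index", "source_path"]


@dataclass
class DatasetTable:
    """Ordered collection of slice records with a shared class vocabulary.

    Parameters
    ----------
    images
        Array of shape ``(n, height, width)``, values in ``[0, 1]``.
    meta
        DataFrame with columns ``class_label``, ``subject_id``, ``volume_id``,
        ``slice_index`` and optionally ``source_path``, one row per image.
    class_set
        Ordered list of class labels; defines one-hot/column order everywhere
        downstream (confusion matrices, probability rows).
    """

    images: np.ndarray
    meta: pd.DataFrame
    class_set: list[str] = field(default_factory=list)
    # relaxed for tables whose labels were deliberately randomized
    check_subject_class: InitVar[bool] = True

    def __post_init__(self, check_subject_class: bool = True) -> None:
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n, H, W), got shape {self.images.shape}")
        if len(self.meta) != len(self.images):
            raise ValueError(
                f"metadata rows ({len(self.meta)}) != images ({len(self.images)})"
            )
        if "source_path" not in self.meta.columns:
            self.meta = self.meta.assign(source_path="")
        if not self.class_set:
            self.class_set = sorted(self.meta["class_label"].unique())
        unknown = set(self.meta["class_label"]) - set(self.class_set)
        if unknown:
            raise ValueError(f"class labels outside class_set: {sorted(unknown)}")
        key = self.meta[["subject_id", "volume_id", "slice_index"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (subject, volume, slice) key: {dup}")
        if check_subject_class:
            # one subject -> one class
            per_subject = self.meta.groupby("subject_id")["class_label"].nunique()
            if (per_subject > 1).any():
                bad = per_subject[per_subject > 1].index.tolist()
                raise ValueError(f"subjects appearing in more than one class: {bad}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    @property
    def labels(self) -> np.ndarray:
        """Class labels as an object array aligned with ``images``."""
        return self.meta["class_label"].to_numpy()

    @property
    def label_indices(self) -> np.ndarray:
        """Integer labels (positions in ``class_set``)."""
        lookup = {c: i for i, c in enumerate(self.class_set)}
        return np.fromiter(
            (lookup[c] for c in self.meta["class_label"]), dtype=np.int64, count=len(self)
        )

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def subset(self, indices) -> "DatasetTable":
        """New table containing the given row positions, class_set preserved."""
        idx = np.asarray(indices, dtype=np.int64)
        return DatasetTable(
            images=self.images[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            class_set=list(self.class_set),
        )

    def with_labels(self, new_labels, shadow_column: str = "original_label") -> "DatasetTable":
        """Copy of the table with ``class_label`` replaced; originals kept in a shadow column."""
        meta = self.meta.copy()
        if shadow_column not in meta.columns:
            meta[shadow_column] = meta["class_label"]
        meta["class_label"] = list(new_labels)
        return DatasetTable(images=self.images, meta=meta, class_set=list(self.class_set),
                            check_subject_class=False)

    def manifest(self) -> pd.DataFrame:
        """Manifest frame (path, class, subject_id, volume_id, slice_index)."""
        return pd.DataFrame(
            {
                "path": self.meta["source_path"],
                "class": self.meta["class_label"],
                "subject_id": self.meta["subject_id"],
                "volume_id": self.meta["volume_id"],
                "slice_index": self.meta["slice_index"],
            }
        )


def concat_tables(tables: list[DatasetTable]) -> DatasetTable:
    if not tables:
        raise ValueError("cannot concatenate an empty list of tables")
    class_set = list(tables[0].class_set)
    for t in tables[1:]:
        for c in t.class_set:
            if c not in class_set:
                class_set.append(c)
    return DatasetTable(
        images=np.concatenate([t.images for t in tables]),
        meta=pd.concat([t.meta for t in tables], ignore_index=True),
        class_set=class_set,
    )
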
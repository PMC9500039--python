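"""Synthetic volumetric-slice datasets with controllable leakage structure.

Emulates the statistical signature of stacks of tomographic cross-sections
(e.g. OCT b-scans): within a volume, consecutive slices share both the
underlying tissue structure and a large fraction of the speckle-like noise
field, so adjacent slices are far more similar to each other than images
from different subjects are. Each image is composed of

* a smooth class template (shared by every subject of a class, the signal a
  classifier should learn), with a small class-dependent mean-intensity
  offset so even a trivial intensity feature carries class information;
* a smooth subject-specific appearance field (shared by all of a subject's
  slices — the component that leaks across a per-image split);
* a smooth volume-structure field that evolves along the slice axis as a
  stationary AR(1) process with per-slice correlation ``exp(-slice_drift)``
  (zero drift => identical underlying structure across the volume; large
  drift => structurally independent slices);
* multiplicative log-normal speckle whose noise field follows an AR(1)
  process along the slice axis with coefficient ``noise_share``, so a
  fraction of the noise is carried over between adjacent slices.

Pixels are quantised to 8 bits (then rescaled to [0, 1]) so that a config +
seed pair produces bit-identical data across runs and platforms and writing
to PNG is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .table import DatasetTable

# internal scale factors mapping the dimensionless config amplitudes onto
# pixel-intensity standard deviations; chosen so defaults stay inside [0,1]
# with little clipping
_CLASS_FIELD_SCALE = 0.15
_CLASS_MEAN_SCALE = 0.10
_SUBJECT_FIELD_SCALE = 0.12
_VOLUME_FIELD_SCALE = 0.10
_BASE_LEVEL = 0.5


@dataclass
class SyntheticConfig:
    """Generative recipe for one synthetic dataset.

    The default hierarchy (2 classes x 10 subjects x 1 volume x 20 slices of
    64 x 64 pixels) is the desk-scale leaky condition used throughout the
    analysis scripts: many redundant slices per subject and a
    subject-specific appearance stronger than the class signal
    (subject_effect 1.5 vs class_effect 0.3), the regime in which slice-wise
    splitting lets a classifier ride subject identity instead of class
    structure.
    """

    n_classes: int = 2
    subjects_per_class: int = 10
    volumes_per_subject: int = 1
    slices_per_volume: int = 20
    image_height: int = 64
    image_width: int = 64
    class_effect: float = 0.3
    subject_effect: float = 1.5
    slice_drift: float = 0.02
    noise_sigma: float = 0.4
    noise_share: float = 0.8
    seed: int = 0
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_classes", "subjects_per_class", "volumes_per_subject",
                     "slices_per_volume", "image_height", "image_width"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"SyntheticConfig.{name} must be a positive integer, got {v!r}")
        if self.n_classes < 2:
            raise ValueError("SyntheticConfig.n_classes must be >= 2")
        if self.subjects_per_class < 2:
            raise ValueError("SyntheticConfig.subjects_per_class must be >= 2")
        for name in ("class_effect", "subject_effect", "slice_drift", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"SyntheticConfig.{name} must be >= 0")
        if not 0.0 <= self.noise_share <= 1.0:
            raise ValueError("SyntheticConfig.noise_share must lie in [0, 1]")
        if not self.class_names:
            self.class_names = [f"class{k}" for k in range(self.n_classes)]
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")

    @property
    def n_records(self) -> int:
        return (self.n_classes * self.subjects_per_class
                * self.volumes_per_subject * self.slices_per_volume)


def _smooth_field(rng: np.random.Generator, h: int, w: int,
                  center: bool = False) -> np.ndarray:
    """Unit-variance smooth random field (low-pass-filtered white noise).

    ``center=True`` removes the spatial mean, yielding a pure-texture field
    that does not shift the image's mean intensity.
    """
    sigma = max(min(h, w) / 12.0, 1.0)
    raw = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma, mode="reflect")
    if center:
        raw = raw - raw.mean()
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _entity_rng(seed: int, *key: int) -> np.random.Generator:
    # stable per-entity streams: the field of subject 3 does not change when
    # subjects_per_class grows from 5 to 10
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def generate_dataset(config: SyntheticConfig) -> DatasetTable:
    """Generate the full class/subject/volume/slice hierarchy.

    Returns one record per (class, subject, volume, slice); deterministic in
    ``config.seed`` with 8-bit-quantised pixel values.
    """
    h, w = config.image_height, config.image_width
    n = config.n_records
    images = np.empty((n, h, w), dtype=np.float32)
    meta_rows = []

    class_templates = []
    for k in range(config.n_classes):
        rng = _entity_rng(config.seed, 0, k)
        # structural field plus a class-dependent mean offset, centred over classes
        offset = (k - (config.n_classes - 1) / 2.0) * _CLASS_MEAN_SCALE
        template = config.class_effect * (
            _CLASS_FIELD_SCALE * _smooth_field(rng, h, w) + offset
        )
        class_templates.append(template)

    i = 0
    subject_counter = 0
    for k, cls in enumerate(config.class_names):
        for s in range(config.subjects_per_class):
            subject_id = f"{subject_counter:04d}"
            subject_counter += 1
            srng = _entity_rng(config.seed, 1, k, s)
            subject_field = (config.subject_effect * _SUBJECT_FIELD_SCALE
                             * _smooth_field(srng, h, w, center=True))
            base_subject = _BASE_LEVEL + class_templates[k] + subject_field
            # structural change along the slice axis: stationary AR(1) with
            # per-slice correlation exp(-slice_drift), so slice_drift = 0
            # freezes the structure across the volume and a large drift
            # decorrelates slices entirely
            rho = float(np.exp(-config.slice_drift))
            for v in range(config.volumes_per_subject):
                volume_id = f"{subject_id}v{v:02d}"
                vrng = _entity_rng(config.seed, 2, k, s, v)
                volume_state = _smooth_field(vrng, h, w, center=True)
                noise_state = vrng.standard_normal((h, w))
                for z in range(config.slices_per_volume):
                    if z > 0:
                        volume_state = (rho * volume_state
                                        + np.sqrt(max(1.0 - rho ** 2, 0.0))
                                        * _smooth_field(vrng, h, w, center=True))
                        # AR(1) carry-over of the speckle field between slices
                        innovation = vrng.standard_normal((h, w))
                        noise_state = (config.noise_share * noise_state
                                       + np.sqrt(1.0 - config.noise_share ** 2) * innovation)
                    base = base_subject + _VOLUME_FIELD_SCALE * volume_state
                    if config.noise_sigma > 0:
                        speckle = np.exp(config.noise_sigma * noise_state
                                         - 0.5 * config.noise_sigma ** 2)
                        img = base * speckle
                    else:
                        img = base
                    img = np.clip(img, 0.0, 1.0)
                    # 8-bit quantisation: exact determinism, lossless PNG round-trip
                    images[i] = np.round(img * 255.0).astype(np.float32) / 255.0
                    meta_rows.append(
                        {
                            "class_label": cls,
                            "subject_id": subject_id,
                            "volume_id": volume_id,
                            "slice_index": z,
                            "source_path": "",
                        }
                    )
                    i += 1
    return DatasetTable(images=images, meta=pd.DataFrame(meta_rows),
                        class_set=list(config.class_names))


def pairwise_correlation_tiers(table: DatasetTable) -> dict[str, float]:
    """Mean Pearson correlation between image pairs, by relationship tier.

    Tiers: ``adjacent`` (consecutive slices, same volume), ``same_subject``
    (same subject, different volumes), ``same_class`` (different subjects,
    same class), ``cross_class``. Tiers with no eligible pairs are omitted.
    The leakage argument rests on the ordering
    adjacent > same_subject > same_class > cross_class.
    """
    flat = table.images.reshape(len(table), -1).astype(np.float64)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    norms[norms == 0] = 1.0
    flat /= norms[:, None]
    corr = flat @ flat.T

    meta = table.meta
    subj = meta["subject_id"].to_numpy()
    vol = meta["volume_id"].to_numpy()
    cls = meta["class_label"].to_numpy()
    sl = meta["slice_index"].to_numpy()

    n = len(table)
    iu, ju = np.triu_indices(n, k=1)
    same_vol = vol[iu] == vol[ju]
    adjacent = same_vol & (np.abs(sl[iu] - sl[ju]) == 1)
    same_subj = (subj[iu] == subj[ju]) & ~same_vol
    same_class = (cls[iu] == cls[ju]) & (subj[iu] != subj[ju])
    cross_class = cls[iu] != cls[ju]

    tiers = {}
    for name, mask in (("adjacent", adjacent), ("same_subject", same_subj),
                       ("same_class", same_class), ("cross_class", cross_class)):
        if mask.any():
            tiers[name] = float(corr[iu[mask], ju[mask]].mean())
    return tiers


def write_dataset_tree(table: DatasetTable, root, layout: str,
                       splits=None) -> pd.DataFrame:
    """Write the table as a PNG directory tree in a published-dataset layout.

    ``aiims-like``: ``root/<class>/<subject>/<volume>/<slice>.png`` —
    per-class, per-subject folders. ``kermany-like``:
    ``root/<split>/<class>/<CLASS>-<subject>-<sliceindex>.png`` with a split
    per record (default all ``train``). Returns the manifest of written
    paths; refuses to overwrite an existing file.
    """
    from PIL import Image

    if len(table) == 0:
        raise ValueError("refusing to write an empty dataset table")
    if layout not in ("aiims-like", "kermany-like"):
        raise ValueError(f"unknown layout {layout!r}")
    root = Path(root)
    if splits is None:
        splits = ["train"] * len(table)
    splits = list(splits)
    if len(splits) != len(table):
        raise ValueError("splits must provide one entry per record")

    rows = []
    seen = set()
    for i in range(len(table)):
        rec = table.meta.iloc[i]
        if layout == "aiims-like":
            path = (root / str(rec.class_label) / str(rec.subject_id)
                    / str(rec.volume_id) / f"{int(rec.slice_index):04d}.png")
        else:
            fname = f"{rec.class_label}-{rec.subject_id}-{int(rec.slice_index)}.png"
            path = root / splits[i] / str(rec.class_label) / fname
        if path in seen or path.exists():
            raise FileExistsError(f"output filename collision: {path}")
        seen.add(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pixels = np.round(table.images[i] * 255.0).astype(np.uint8)
        Image.fromarray(pixels, mode="L").save(path)
        rows.append(
            {
                "path": str(path),
                "class": rec.class_label,
                "subject_id": rec.subject_id,
                "volume_id": rec.volume_id,
                "slice_index": int(rec.slice_index),
                "split": splits[i],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest
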
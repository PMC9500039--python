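"""Loaders for the published OCT dataset layouts (and synthetic mimics).

Two folder conventions are supported:

* pre-split trees (Kermany OCT2017 style): ``root/<split>/<class>/`` with
  subject identity encoded in ``CLASS-subjectID-bscanID`` filenames;
* subject-wise trees (AIIMS / Srinivasan style): ``root/<class>/<subject>``
  (optionally ``/<volume>``) folders of images, subject identity taken from
  the folder names.

Subject identity is what leakage audits run on, so both loaders are careful
to recover it losslessly and to namespace folder-derived subject IDs by
class (two classes may both contain a folder ``Patient_1``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .table import DatasetTable

IMAGE_EXTENSIONS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ParsedName:
    class_label: str
    subject_id: str
    slice_id: str


class FilenameParseError(ValueError):
    pass


def parse_kermany_filename(name: str) -> ParsedName:
    """Parse a ``CLASS-subjectID-bscanID`` base filename.

    Splits on the *last two* hyphens so class labels containing hyphens
    survive: ``"DRUSEN-8086850-6.jpeg" -> (DRUSEN, 8086850, 6)``.
    """
    stem = Path(name).name
    stem = re.sub(r"\.[A-Za-z0-9]+$", "", stem)
    parts = stem.rsplit("-", 2)
    if len(parts) != 3 or not all(parts):
        raise FilenameParseError(
            f"cannot parse {name!r}: expected CLASS-subjectID-bscanID"
        )
    return ParsedName(class_label=parts[0], subject_id=parts[1], slice_id=parts[2])


def standardize_image(image: np.ndarray, target_height: int = 128,
                      target_width: int = 128) -> np.ndarray:
    """Grayscale, bilinear-resized, [0, 1]-scaled copy of an image.

    Accepts 2D grayscale or RGB(A) input; RGB is converted by channel
    averaging (so equal channels reproduce the single-channel result
    exactly). Integer inputs are scaled by their dtype range.
    """
    from skimage.transform import resize

    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot standardize a zero-sized image")
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float64) / np.iinfo(image.dtype).max
    else:
        image = image.astype(np.float64)
    if image.ndim == 3:
        image = image[..., :3].mean(axis=2)
    elif image.ndim != 2:
        raise ValueError(f"expected 2D or RGB image, got ndim={image.ndim}")
    if image.shape != (target_height, target_width):
        image = resize(image, (target_height, target_width), order=1,
                       mode="reflect", anti_aliasing=False, preserve_range=True)
    return np.clip(image, 0.0, 1.0).astype(np.float32)


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", name)]


def _iter_image_files(folder: Path):
    return sorted(
        (p for p in folder.iterdir()
         if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS),
        key=lambda p: _natural_key(p.name),
    )


def _read_image(path: Path, target_height, target_width) -> np.ndarray:
    with Image.open(path) as img:
        arr = np.asarray(img)
    return standardize_image(arr, target_height, target_width)


def load_kermany_split(root, target_height: int = 128, target_width: int = 128,
                       splits=("train", "val", "test")) -> dict[str, DatasetTable]:
    """Load a pre-split ``root/<split>/<class>/CLASS-subject-bscan.*`` tree.

    Returns one table per split directory present. Subject and slice come
    from the filename; ``volume_id`` is set to the subject ID because this
    layout does not expose volumes. Unreadable images are skipped with a
    warning and counted in the per-table ``attrs['n_skipped']``.
    """
    root = Path(root)
    present = [s for s in splits if (root / s).is_dir()]
    if not present:
        raise FileNotFoundError(f"no split subdirectories {list(splits)} under {root}")
    tables: dict[str, DatasetTable] = {}
    for split in present:
        split_dir = root / split
        class_dirs = sorted((d for d in split_dir.iterdir() if d.is_dir()),
                            key=lambda d: d.name)
        images, rows, skipped = [], [], 0
        for class_dir in class_dirs:
            for path in _iter_image_files(class_dir):
                try:
                    parsed = parse_kermany_filename(path.name)
                    img = _read_image(path, target_height, target_width)
                except (FilenameParseError, OSError) as exc:
                    warnings.warn(f"skipping {path}: {exc}", stacklevel=2)
                    skipped += 1
                    continue
                images.append(img)
                rows.append(
                    {
                        "class_label": parsed.class_label,
                        "subject_id": parsed.subject_id,
                        "volume_id": parsed.subject_id,
                        "slice_index": int(parsed.slice_id),
                        "source_path": str(path),
                    }
                )
        if not rows:
            raise ValueError(f"split directory {split_dir} contains no readable images")
        table = DatasetTable(images=np.stack(images), meta=pd.DataFrame(rows))
        table.meta.attrs["n_skipped"] = skipped
        tables[split] = table
    return tables


def load_subjectwise_tree(root, layout: str = "aiims", target_height: int = 128,
                          target_width: int = 128) -> DatasetTable:
    """Load a ``root/<class>/<subject>[/<volume>]/images`` tree.

    Subject IDs are prefixed with the class folder name to guarantee global
    uniqueness; slice order within a folder follows numeric-aware natural
    sort of the filenames. ``layout`` ({'aiims', 'srinivasan'}) is accepted
    for provenance; both use the same folder convention.
    """
    if layout not in ("aiims", "srinivasan"):
        raise ValueError(f"unknown subject-wise layout {layout!r}")
    root = Path(root)
    class_dirs = sorted((d for d in root.iterdir() if d.is_dir()), key=lambda d: d.name)
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    images, rows, skipped = [], [], 0
    for class_dir in class_dirs:
        subject_dirs = sorted((d for d in class_dir.iterdir() if d.is_dir()),
                              key=lambda d: _natural_key(d.name))
        if not subject_dirs:
            raise ValueError(f"class folder {class_dir} contains no subject folders")
        for subject_dir in subject_dirs:
            subject_id = f"{class_dir.name}/{subject_dir.name}"
            volume_dirs = sorted((d for d in subject_dir.iterdir() if d.is_dir()),
                                 key=lambda d: _natural_key(d.name))
            if volume_dirs:
                sources = [(d, f"{subject_id}/{d.name}") for d in volume_dirs]
            else:
                sources = [(subject_dir, subject_id)]
            for folder, volume_id in sources:
                for slice_index, path in enumerate(_iter_image_files(folder)):
                    try:
                        img = _read_image(path, target_height, target_width)
                    except OSError as exc:
                        warnings.warn(f"skipping {path}: {exc}", stacklevel=2)
                        skipped += 1
                        continue
                    images.append(img)
                    rows.append(
                        {
                            "class_label": class_dir.name,
                            "subject_id": subject_id,
                            "volume_id": volume_id,
                            "slice_index": slice_index,
                            "source_path": str(path),
                        }
                    )
    if not rows:
        raise ValueError(f"no readable images under {root}")
    table = DatasetTable(images=np.stack(images), meta=pd.DataFrame(rows))
    table.meta.attrs["n_skipped"] = skipped
    return table
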
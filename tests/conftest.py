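import numpy as np
import pandas as pd
import pytest

from octsplit import DatasetTable, SyntheticConfig, generate_dataset


def make_meta_table(n_classes=2, subjects_per_class=5, volumes_per_subject=1,
                    slices_per_volume=10, image_size=4) -> DatasetTable:
    """Metadata-only table (tiny blank images) for split-logic tests."""
    rows = []
    sid = 0
    for k in range(n_classes):
        for s in range(subjects_per_class):
            subject = f"s{sid:03d}"
            sid += 1
            for v in range(volumes_per_subject):
                for z in range(slices_per_volume):
                    rows.append({"class_label": f"c{k}", "subject_id": subject,
                                 "volume_id": f"{subject}v{v}", "slice_index": z,
                                 "source_path": ""})
    meta = pd.DataFrame(rows)
    images = np.zeros((len(meta), image_size, image_size), dtype=np.float32)
    return DatasetTable(images=images, meta=meta)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete synthetic recipe (multi-volume)."""
    return SyntheticConfig(n_classes=2, subjects_per_class=3, volumes_per_subject=2,
                           slices_per_volume=5, image_height=32, image_width=32,
                           seed=7)


@pytest.fixture(scope="session")
def tiny_table(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def default_table():
    """The default leaky study dataset (400 slices, 64x64)."""
    return generate_dataset(SyntheticConfig(seed=0))
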
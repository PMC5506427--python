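"""Reading and writing per-cell image stacks, manifests and feature tables.

A dataset on disk is a directory of per-cell TIFF files plus a ``manifest.csv``
with one row per cell (cell id, sample id, file path(s), channel names, pixel
size).  Images are stored as unsigned 16-bit TIFF pages — either one multi-page
file per cell (pages follow the declared channel order) or one single-page file
per channel — and are converted to float64 on load.  Integer-valued pixels in
[0, 65535] round-trip losslessly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: μm per pixel edge assumed when a manifest does not state one.
DEFAULT_PIXEL_SIZE_UM = 0.5

_MANIFEST_COLUMNS = ["cell_id", "sample_id", "files", "channels", "pixel_size_um"]
_PATH_SEP = "|"


class DatasetError(ValueError):
    """Raised for malformed manifests, missing files or inconsistent images."""


@dataclass
class CellRecord:
    """One cell's multi-channel image stack plus metadata.

    ``channels`` maps channel name to a 2-D non-negative grayscale image; all
    channels of a cell share one shape and one pixel size.  The bright-field
    channel ``"BF"`` is always required.  ``ground_truth`` carries phenotype
    labels for synthetic cells and is absent for real data.
    """

    cell_id: str
    sample_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if "BF" not in self.channels:
            raise DatasetError(f"cell {self.cell_id!r}: required channel 'BF' missing")
        if not self.pixel_size_um > 0:
            raise DatasetError(f"cell {self.cell_id!r}: pixel_size_um must be > 0")
        shapes = {ch: np.asarray(img).shape for ch, img in self.channels.items()}
        ref = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise DatasetError(f"cell {self.cell_id!r}: channel images must be 2-D")
        if any(s != ref for s in shapes.values()):
            raise DatasetError(
                f"cell {self.cell_id!r}: channel shapes differ: {shapes}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


def write_dataset(
    cells: Iterable[CellRecord], out_dir: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write cells as one multi-page uint16 TIFF each plus a manifest CSV.

    Returns the manifest path.  Pixel values must be finite; they are rounded
    to the nearest integer and clipped into [0, 65535] on disk, so
    integer-valued inputs round-trip exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    seen: set[str] = set()
    for cell in cells:
        if cell.cell_id in seen:
            raise DatasetError(f"duplicate cell_id {cell.cell_id!r}")
        seen.add(cell.cell_id)
        stack = []
        for ch, img in cell.channels.items():
            arr = np.asarray(img, dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise DatasetError(
                    f"cell {cell.cell_id!r}: non-finite pixels in channel {ch!r}"
                )
            stack.append(np.clip(np.round(arr), 0, 65535).astype(np.uint16))
        fname = f"{cell.cell_id}.tiff"
        tifffile.imwrite(out_dir / fname, np.stack(stack), photometric="minisblack")
        rows.append(
            {
                "cell_id": cell.cell_id,
                "sample_id": cell.sample_id,
                "files": fname,
                "channels": _PATH_SEP.join(cell.channel_names),
                "pixel_size_um": cell.pixel_size_um,
            }
        )
    manifest_path = out_dir / manifest_name
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def _load_images(paths: Sequence[Path], channels: Sequence[str], cell_id: str) -> dict:
    if len(paths) == 1 and len(channels) > 1:
        pages = tifffile.imread(paths[0])
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != len(channels):
            raise DatasetError(
                f"cell {cell_id!r}: {paths[0].name} has {pages.shape[0]} pages "
                f"but {len(channels)} channels declared"
            )
        imgs = [np.asarray(p) for p in pages]
    elif len(paths) == len(channels):
        imgs = [np.asarray(tifffile.imread(p)).squeeze() for p in paths]
    else:
        raise DatasetError(
            f"cell {cell_id!r}: {len(paths)} files for {len(channels)} channels"
        )
    return {ch: img.astype(np.float64) for ch, img in zip(channels, imgs)}


def read_dataset(manifest_path: str | Path) -> list[CellRecord]:
    """Load a dataset in manifest order.

    Raises :class:`DatasetError` (naming the cell) on missing files or
    channel-shape mismatches.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype={"cell_id": str, "sample_id": str})
    missing_cols = [c for c in _MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"manifest missing columns: {missing_cols}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise DatasetError(f"duplicate cell_id {dup!r} in manifest")
    cells = []
    for row in df.itertuples(index=False):
        channels = str(row.channels).split(_PATH_SEP)
        paths = [base / p for p in str(row.files).split(_PATH_SEP)]
        for p in paths:
            if not p.exists():
                raise DatasetError(f"cell {row.cell_id!r}: file not found: {p}")
        px = (
            float(row.pixel_size_um)
            if "pixel_size_um" in df.columns and np.isfinite(row.pixel_size_um)
            else DEFAULT_PIXEL_SIZE_UM
        )
        cells.append(
            CellRecord(
                cell_id=str(row.cell_id),
                sample_id=str(row.sample_id),
                channels=_load_images(paths, channels, str(row.cell_id)),
                pixel_size_um=px,
            )
        )
    return cells


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell feature table as CSV (9+ significant digits).

    Missing features are written as empty fields and survive a round-trip as
    NaN — never as silent zeros.
    """
    if "cell_id" not in table.columns:
        raise DatasetError("feature table must have a cell_id column")
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise DatasetError(f"duplicate cell_id {dup!r} in feature table")
    return df
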
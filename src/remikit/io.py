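"""Reading and writing multi-round image collections and tabular results.

The on-disk exchange layout is deliberately plain: multi-page grayscale
TIFFs (one file per round, one page per channel) indexed by a tab-separated
manifest with columns ``file  page  round  channel  label``, plus CSV for
every table.  Intensities are stored as unsigned integers and promoted to
float64 at this module's boundary; all downstream code works in float.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = ["MultiRoundDataset", "read_dataset", "write_dataset",
           "write_table", "read_table"]

MANIFEST_COLUMNS = ("file", "page", "round", "channel", "label")


@dataclass
class MultiRoundDataset:
    """Ordered collection of 2-D grayscale images indexed by (round, channel).

    Rounds are 1-based and contiguous; every image shares one shape.
    ``labels`` maps each channel name to its antibody/protein label;
    ``pixel_size`` is the physical pixel edge (arbitrary length unit,
    optional).
    """

    images: dict[tuple[int, str], np.ndarray]
    labels: dict[str, str] = field(default_factory=dict)
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("dataset has no images")
        shapes = {img.shape for img in self.images.values()}
        if len(shapes) > 1:
            bad = sorted(
                f"(round {r}, channel {c!r}): {img.shape}"
                for (r, c), img in self.images.items()
            )
            raise ValueError("images disagree on shape: " + "; ".join(bad))
        rounds = self.rounds
        if rounds != list(range(1, len(rounds) + 1)):
            raise ValueError(f"round indices must be contiguous from 1, got {rounds}")

    @property
    def rounds(self) -> list[int]:
        return sorted({r for r, _ in self.images})

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, c in self.images:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    def get(self, round_index: int, channel: str) -> np.ndarray:
        try:
            return self.images[(round_index, channel)]
        except KeyError:
            raise KeyError(
                f"no image for round {round_index}, channel {channel!r}"
            ) from None


def read_dataset(manifest_path: str | Path) -> MultiRoundDataset:
    """Load a dataset from its manifest.

    Pixel data are read as-is (no scaling) and promoted to float64.
    Missing files/pages raise ``FileNotFoundError``/``IndexError`` naming
    the offending entry; shape disagreements raise ``ValueError`` listing
    the entries.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")

    base = manifest_path.parent
    images: dict[tuple[int, str], np.ndarray] = {}
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        path = base / str(row["file"])
        if not path.exists():
            raise FileNotFoundError(f"manifest entry refers to missing file: {path}")
        with tifffile.TiffFile(path) as tf:
            page = int(row["page"])
            if page >= len(tf.pages):
                raise IndexError(
                    f"{path} has {len(tf.pages)} pages; manifest asks for page {page}"
                )
            arr = tf.pages[page].asarray()
        key = (int(row["round"]), str(row["channel"]))
        if key in images:
            raise ValueError(f"duplicate manifest entry for round/channel {key}")
        images[key] = np.asarray(arr, dtype=np.float64)
        labels[str(row["channel"])] = str(row["label"])
    return MultiRoundDataset(images=images, labels=labels)


def write_dataset(dataset: MultiRoundDataset, out_dir: str | Path) -> Path:
    """Write a dataset in the manifest + per-round multi-page TIFF layout.

    Float images are rounded and stored as uint16.  Returns the manifest
    path; ``read_dataset`` of that path reproduces the pixel data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in dataset.rounds:
        chans = [c for (rr, c) in dataset.images if rr == r]
        pages = []
        for page, c in enumerate(chans):
            img = dataset.images[(r, c)]
            pages.append(np.round(np.clip(img, 0, 2**16 - 1)).astype(np.uint16))
            rows.append((f"round{r:02d}.tif", page, r, c, dataset.labels.get(c, c)))
        tifffile.imwrite(out_dir / f"round{r:02d}.tif", np.stack(pages),
                         photometric="minisblack")
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return manifest


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write tabular records as CSV with a header row, floats at full precision.

    ``columns`` fixes the header explicitly — required to emit a
    header-only file from an empty record list.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and len({tuple(r.keys()) for r in rows}) > 1:
            raise ValueError("records do not share a header")
        df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
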
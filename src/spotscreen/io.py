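"""Dataset persistence: 16-bit TIFFs plus layout and ground-truth CSVs.

One TIFF per channel per field, named ``<rep>_<position>_<sub>_<channel>.tif``,
with ``layout.csv`` mapping fields to image files and, when ground truth
is available, ``truth_cells.csv`` / ``truth_fields.csv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .layout import validate_layout
from .synth import CLASSES, FieldImage, GroundTruth

__all__ = ["write_dataset", "read_dataset"]

CHANNEL_ORDER = ("nuclei", "marker", "cargo")


def _stem(f: FieldImage) -> str:
    return f"{f.replicate}_{f.position}_{f.subposition}"


def write_dataset(
    fields: list[FieldImage],
    truths: list[GroundTruth] | None,
    directory: str | Path,
) -> Path:
    """Write fields (and truth, if given) to ``directory``; returns it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layout_rows = []
    cell_rows = []
    field_rows = []
    for i, f in enumerate(fields):
        row = {
            "replicate": f.replicate,
            "platform": f.platform,
            "position": f.position,
            "subposition": f.subposition,
            "condition": f.condition,
        }
        for ch in CHANNEL_ORDER:
            key = f"{ch}_path"
            if ch in f.channels:
                name = f"{_stem(f)}_{ch}.tif"
                tifffile.imwrite(directory / name, f.channels[ch].astype(np.uint16))
                row[key] = name
            else:
                row[key] = ""
        layout_rows.append(row)
        if truths is not None:
            t = truths[i]
            for j, cell in t.cells.iterrows():
                cell_rows.append(
                    {
                        "replicate": f.replicate,
                        "position": f.position,
                        "subposition": f.subposition,
                        "cell_index": j,
                        **cell.to_dict(),
                    }
                )
            fr = t.fractions()
            field_rows.append(
                {
                    "replicate": f.replicate,
                    "position": f.position,
                    "subposition": f.subposition,
                    "n_cells": t.n_cells,
                    "n_dropped": t.n_dropped,
                    **{f"frac_{c}": fr[k] for k, c in enumerate(CLASSES)},
                    "mean_cargo": t.mean_cargo(),
                }
            )
    pd.DataFrame(layout_rows).to_csv(directory / "layout.csv", index=False)
    if truths is not None:
        pd.DataFrame(cell_rows).to_csv(directory / "truth_cells.csv", index=False)
        pd.DataFrame(field_rows).to_csv(directory / "truth_fields.csv", index=False)
    return directory


def read_dataset(
    directory: str | Path,
) -> tuple[list[FieldImage], list[GroundTruth] | None]:
    """Read a dataset written by :func:`write_dataset`.

    Raises a ValueError naming the offending row for malformed layouts and
    an OSError naming the file for unreadable TIFFs.
    """
    directory = Path(directory)
    layout_path = directory / "layout.csv"
    if not layout_path.exists():
        raise FileNotFoundError(f"no layout.csv in {directory}")
    layout = pd.read_csv(layout_path, keep_default_na=False)
    validate_layout(layout)
    fields = []
    for i, row in enumerate(layout.itertuples(index=False), start=1):
        channels = {}
        for ch in CHANNEL_ORDER:
            name = getattr(row, f"{ch}_path", "")
            if not name:
                continue
            path = directory / name
            try:
                channels[ch] = tifffile.imread(path)
            except Exception as exc:  # corrupt or missing file
                raise OSError(f"cannot read image {path.name!r}: {exc}") from exc
        if "nuclei" not in channels:
            raise ValueError(f"layout row {i}: no nuclei image")
        fields.append(
            FieldImage(
                channels=channels,
                platform=row.platform,
                replicate=int(row.replicate),
                position=str(row.position),
                subposition=int(row.subposition),
                condition=str(row.condition),
            )
        )
    truths = None
    cells_path = directory / "truth_cells.csv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path)
        truths = []
        for f in fields:
            sel = cells[
                (cells["replicate"] == f.replicate)
                & (cells["position"] == f.position)
                & (cells["subposition"] == f.subposition)
            ]
            truths.append(
                GroundTruth(
                    cells=sel[
                        ["class", "centroid_r", "centroid_c", "footprint_px", "ring_mean"]
                    ].reset_index(drop=True)
                )
            )
    return fields, truths
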
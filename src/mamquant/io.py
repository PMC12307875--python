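"""File I/O: multi-page TIFF images, manifests, traces, plates and tables.

Images travel as 16-bit multi-page TIFF (one page per channel, channel
labels in the page descriptions / a JSON sidecar); tabular data as CSV/TSV
with header rows. These helpers keep every analysis module free of disk
concerns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .datatypes import AtpPlate, MultiChannelImage, TracePair

_UINT16_MAX = 65535

# fixed intensity scale for 16-bit storage; rendered images live in [0, ~1.3]
_SCALE = 20000.0


def write_image(path: str | Path, image: MultiChannelImage, sidecar: dict | None = None) -> None:
    """Write one multi-channel image as a multi-page 16-bit TIFF.

    Channel labels, pixel size, sample/group and any extra ground-truth
    ``sidecar`` payload go to ``<path>.json`` next to the TIFF.
    """
    path = Path(path)
    labels = list(image.channels)
    stack = np.stack(
        [np.clip(image.channels[c] * _SCALE, 0, _UINT16_MAX) for c in labels]
    ).astype(np.uint16)
    tifffile.imwrite(path, stack)
    meta = {
        "channels": labels,
        "pixel_size_um": image.pixel_size,
        "sample_id": image.sample_id,
        "group": image.group,
        "intensity_scale": _SCALE,
    }
    if sidecar:
        meta["ground_truth"] = sidecar
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_image(path: str | Path) -> MultiChannelImage:
    """Read a multi-page TIFF written by :func:`write_image`."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        labels = meta["channels"]
        scale = meta.get("intensity_scale", _SCALE)
        return MultiChannelImage(
            {lab: stack[i].astype(float) / scale for i, lab in enumerate(labels)},
            pixel_size=meta.get("pixel_size_um", 1.0),
            sample_id=meta.get("sample_id", path.stem),
            group=meta.get("group", ""),
        )
    labels = [f"ch{i}" for i in range(stack.shape[0])]
    return MultiChannelImage(
        {lab: stack[i].astype(float) for i, lab in enumerate(labels)},
        sample_id=path.stem,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a batch manifest CSV: sample_id, group, plus per-channel paths."""
    manifest = pd.read_csv(path)
    for col in ("sample_id", "group"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    return manifest


def write_traces(path: str | Path, pairs: Sequence[TracePair]) -> None:
    """Write trace pairs as tidy CSV (time, indicator, reference, ids)."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": p.sample_id,
                "group": p.group,
                "time": p.time,
                "indicator": p.indicator,
                "reference": p.reference,
            }
        )
        for p in pairs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[TracePair]:
    """Read trace pairs from tidy CSV, one pair per sample_id."""
    table = pd.read_csv(path)
    needed = {"sample_id", "time", "indicator", "reference"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"trace CSV is missing columns: {sorted(missing)}")
    pairs = []
    for sample_id, df in table.groupby("sample_id", sort=True):
        df = df.sort_values("time")
        pairs.append(
            TracePair(
                df["time"].to_numpy(float),
                df["indicator"].to_numpy(float),
                df["reference"].to_numpy(float),
                sample_id=str(sample_id),
                group=str(df["group"].iloc[0]) if "group" in df else "",
            )
        )
    return pairs


def write_plates(path: str | Path, plates: Sequence[AtpPlate]) -> None:
    """Write plates as tidy CSV (sample_id, group, condition, rlu)."""
    rows = [
        {"sample_id": p.sample_id, "group": p.group, "condition": cond, "rlu": v}
        for p in plates
        for cond, values in p.replicates.items()
        for v in values
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plates(path: str | Path) -> list[AtpPlate]:
    """Read plates from tidy CSV written by :func:`write_plates`."""
    table = pd.read_csv(path)
    needed = {"sample_id", "group", "condition", "rlu"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"plate CSV is missing columns: {sorted(missing)}")
    plates = []
    for (sample_id, group), df in table.groupby(["sample_id", "group"], sort=True):
        replicates = {
            cond: sub["rlu"].to_numpy(float) for cond, sub in df.groupby("condition")
        }
        plates.append(AtpPlate(sample_id=str(sample_id), group=str(group), replicates=replicates))
    return plates


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene statistics TSV (columns: gene, log2fc, pvalue)."""
    return pd.read_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line, ignoring blanks."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]
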
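"""Shared in-memory containers used across the quantification modules.

Conventions: images are 2D ``numpy`` arrays indexed ``(row, col)``; physical
scale is a single isotropic ``pixel_size`` in µm/px; masks are boolean arrays;
tables are ``pandas`` DataFrames with documented column schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class MultiChannelImage:
    """Registered 2D intensity grids sharing one coordinate system.

    Parameters
    ----------
    channels
        Mapping from channel label (e.g. ``"er"``, ``"mito"``, ``"protein"``)
        to a 2D non-negative float array. All channels must share one shape.
    pixel_size
        Physical pixel size in µm/px.
    sample_id, group
        Sample identifier and experimental group label (e.g. ``"control"`` /
        ``"stress"``); used by batch-level statistics.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have differing shapes: {sorted(shapes)}")
        for label, ch in self.channels.items():
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {label!r} contains non-finite values")
            if np.any(ch < 0):
                raise ValueError(f"channel {label!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabeledMask:
    """Binary object map plus the preprocessing provenance that produced it.

    ``n_objects`` is the connected-component count under the connectivity
    recorded in ``provenance`` (8-connected by default); no surviving
    component is smaller than ``provenance["min_size"]`` pixels.
    """

    mask: np.ndarray
    n_objects: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class OverlapMeasurement:
    """Foreground pixel counts of two (or three) masks and their intersection.

    ``overlap_pixels`` is the number of coordinates foreground in every mask
    considered; invariantly ``overlap_pixels <= min(pixels_a, pixels_b)``.
    ``pixels_c`` is set only for three-way measurements.
    """

    pixels_a: int
    pixels_b: int
    overlap_pixels: int
    sample_id: str = ""
    group: str = ""
    pixels_c: Optional[int] = None

    def __post_init__(self) -> None:
        counts = [self.pixels_a, self.pixels_b, self.overlap_pixels]
        if self.pixels_c is not None:
            counts.append(self.pixels_c)
        if any(c < 0 for c in counts):
            raise ValueError("pixel counts must be non-negative")
        bound = min(self.pixels_a, self.pixels_b)
        if self.pixels_c is not None:
            bound = min(bound, self.pixels_c)
        if self.overlap_pixels > bound:
            raise ValueError("overlap cannot exceed the smallest mask")


@dataclass
class TracePair:
    """Indicator and reference time series sampled on one shared clock."""

    time: np.ndarray
    indicator: np.ndarray
    reference: np.ndarray
    indicator_label: str = "indicator"
    reference_label: str = "reference"
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.indicator = np.asarray(self.indicator, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        n = len(self.time)
        if n < 2:
            raise ValueError("a trace needs at least 2 timepoints")
        if len(self.indicator) != n or len(self.reference) != n:
            raise ValueError("time, indicator and reference must share one length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class AtpPlate:
    """Replicate luminescence (RLu) per inhibitor condition for one sample.

    Conditions follow the four-arm inhibitor design: vehicle ``control``,
    2-deoxy-D-glucose ``DG``, oligomycin A ``OA`` and the combined ``DGOA``.
    """

    sample_id: str
    group: str
    replicates: dict[str, np.ndarray]

    CONDITIONS = ("control", "DG", "OA", "DGOA")

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for cond, values in self.replicates.items():
            if cond not in self.CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}; expected one of {self.CONDITIONS}")
            arr = np.atleast_1d(np.asarray(values, dtype=float))
            if arr.size < 1:
                raise ValueError(f"condition {cond!r} has no replicates")
            if np.any(arr < 0):
                raise ValueError(f"condition {cond!r} has negative luminescence")
            clean[cond] = arr
        self.replicates = clean

    def condition_mean(self, cond: str) -> float:
        return float(np.mean(self.replicates[cond]))
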
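"""Tandem-fluorophore reporter and co-positivity readouts.

Covers three vesicle-level quantifications: the percentage of red-only
puncta of a tandem mCherry-EGFP autophagy reporter (green quenches in
acidic compartments, so red-only marks autolysosomal delivery), the
red-only fluorescence-intensity percentage of a mitochondrially targeted
tandem reporter, and counts of marker puncta (LC3 / CD63) whose footprint
also contains mitochondrial signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .colocalization import CONNECTIVITY, DEFAULT_MIN_SIZE, binarize_and_filter
from .datatypes import LabeledMask

#: robust green-positivity factor: a punctum is green-positive when its mean
#: green intensity exceeds background median + GREEN_K * background MAD
GREEN_K = 3.0


@dataclass
class Punctum:
    centroid: tuple[float, float]
    area_px: int
    mean_intensity: dict[str, float]
    coords: np.ndarray  # (n, 2) pixel coordinates of the footprint
    classification: Optional[str] = None  # "red_only" | "dual"


def detect_puncta(
    red: np.ndarray,
    green: np.ndarray,
    threshold: float | str = "otsu",
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[Punctum]:
    """Segment puncta on the red channel and record both channels' means.

    Puncta are 8-connected components of the thresholded red channel passing
    the small-object cutoff; per punctum the mean red and green intensities
    over its footprint are recorded for later classification.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError(f"channel shapes differ: {red.shape} vs {green.shape}")
    mask = binarize_and_filter(red, threshold=threshold, min_size=min_size).mask
    labels = cc_label(mask, connectivity=CONNECTIVITY)
    puncta = []
    for region in regionprops(labels):
        coords = region.coords
        puncta.append(
            Punctum(
                centroid=tuple(region.centroid),
                area_px=int(region.area),
                mean_intensity={
                    "red": float(red[coords[:, 0], coords[:, 1]].mean()),
                    "green": float(green[coords[:, 0], coords[:, 1]].mean()),
                },
                coords=coords,
            )
        )
    return puncta


def green_background_threshold(
    green: np.ndarray,
    red_mask: np.ndarray,
    k: float = GREEN_K,
) -> float:
    """Robust green-positivity threshold: background median + k * MAD.

    Background pixels are those outside the red-channel foreground. With a
    flat background (MAD 0) the threshold degenerates to the background
    median, so any green signal strictly above background counts positive.
    """
    bg = np.asarray(green, dtype=float)[~np.asarray(red_mask, dtype=bool)]
    if bg.size == 0:
        raise ValueError("no background pixels outside the red mask")
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + k * mad


def classify_puncta(
    puncta: Sequence[Punctum],
    green_threshold: float,
) -> list[Punctum]:
    """Label each punctum ``dual`` (green-positive) or ``red_only``.

    A punctum is dual iff its mean green intensity strictly exceeds the
    background-derived threshold; otherwise the green fluorophore is taken
    as quenched and the punctum is red-only. The comparison carries a tiny
    relative tolerance so a punctum sitting exactly at background is not
    pushed over the line by floating-point accumulation.
    """
    tol = 1e-9 * (abs(green_threshold) + 1.0)
    for p in puncta:
        dual = p.mean_intensity["green"] > green_threshold + tol
        p.classification = "dual" if dual else "red_only"
    return list(puncta)


def red_puncta_percentage(puncta: Sequence[Punctum]) -> tuple[Optional[float], str]:
    """Per-cell red-puncta percentage: 100 * (#red_only / #total).

    Returns ``(value, reason)``; the value is absent for a cell with zero
    detected puncta, where the ratio is undefined.
    """
    if not puncta:
        return None, "no puncta detected"
    if any(p.classification is None for p in puncta):
        raise ValueError("puncta must be classified first (classify_puncta)")
    n_red = sum(p.classification == "red_only" for p in puncta)
    return 100.0 * n_red / len(puncta), "ok"


def red_only_intensity_percentage(
    red: np.ndarray,
    green: np.ndarray,
    roi: Optional[np.ndarray] = None,
) -> tuple[Optional[float], str]:
    """Red share of total fluorescence: 100 * sum(red) / (sum(red) + sum(green)).

    Computed over the ROI (whole image when None). Absent when the total
    fluorescence in the ROI is zero. Invariant to a common positive rescaling
    of both channels.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError(f"channel shapes differ: {red.shape} vs {green.shape}")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            return None, "empty ROI"
        red, green = red[roi], green[roi]
    total = float(red.sum() + green.sum())
    if total <= 0:
        return None, "zero total fluorescence"
    return 100.0 * float(red.sum()) / total, "ok"


def copositive_puncta_count(
    puncta: Sequence[Punctum],
    mito_mask: LabeledMask | np.ndarray,
    min_overlap_fraction: float = 0.0,
) -> int:
    """Count marker puncta whose footprint also contains mitochondrial signal.

    A punctum counts when its overlap with the mitochondrial foreground is
    at least ``max(1 px, min_overlap_fraction * area)``; the default
    (fraction 0) is the any-overlap rule.
    """
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    mito = mito_mask.mask if isinstance(mito_mask, LabeledMask) else np.asarray(mito_mask, bool)
    count = 0
    for p in puncta:
        overlap = int(mito[p.coords[:, 0], p.coords[:, 1]].sum())
        if overlap >= max(1.0, min_overlap_fraction * p.area_px):
            count += 1
    return count
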
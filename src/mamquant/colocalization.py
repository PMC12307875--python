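"""ER-mitochondria contact (MAM) quantification from fluorescence images.

The pipeline mirrors the classic binarized-overlap workflow: every channel in
a comparison is contrast-adjusted, optionally sharpened and thresholded with
ONE shared parameter set, very small puncta (< 10 px) are removed, and the
contact readout is the number of pixel coordinates foreground in both
binarized channels. Sample-level overlap counts are reported as a fold
change over the control-group mean — the "overlap index" — so the control
group averages to 1 by construction. Pearson's correlation is computed
separately on raw (unbinarized) intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu, unsharp_mask
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, remove_small_objects

from .datatypes import LabeledMask, OverlapMeasurement

#: 8-connectivity for connected components (scikit-image connectivity=2),
#: the common default for diffraction-limited fluorescence puncta.
CONNECTIVITY = 2

#: components strictly smaller than this survive-threshold are removed
DEFAULT_MIN_SIZE = 10


@dataclass
class OverlapIndexResult:
    """Per-sample overlap indices normalized to the control-group mean."""

    indices: dict[str, float]            # sample_id -> overlap index
    groups: dict[str, str]               # sample_id -> group label
    control_group: str
    control_mean_overlap: float
    group_mean: dict[str, float] = field(default_factory=dict)
    group_sem: dict[str, Optional[float]] = field(default_factory=dict)


def preprocess_channel(
    channel: np.ndarray,
    stretch: tuple[float, float] = (0.0, 100.0),
    sharpen: bool = False,
    sharpen_radius: float = 2.0,
    sharpen_amount: float = 1.0,
) -> np.ndarray:
    """Linearly rescale a channel between two percentile bounds into [0, 1].

    ``stretch`` gives (low, high) percentiles; intensities at or below the
    low bound map to 0, at or above the high bound to 1. A degenerate bound
    pair (constant image) maps everything to 0. Optional unsharp masking is
    applied after the stretch with a fixed radius/amount so the whole batch
    sees one operator.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty image")
    low, high = stretch
    if not (0 <= low < high <= 100):
        raise ValueError(f"percentiles must satisfy 0 <= low < high <= 100, got {stretch}")
    lo, hi = np.percentile(channel, [low, high])
    if hi <= lo:
        out = np.zeros_like(channel)
    else:
        out = np.clip((channel - lo) / (hi - lo), 0.0, 1.0)
    if sharpen:
        out = np.clip(unsharp_mask(out, radius=sharpen_radius, amount=sharpen_amount), 0.0, 1.0)
    return out


def preprocess_batch(
    channels: Sequence[np.ndarray],
    stretch: tuple[float, float] = (0.0, 100.0),
    sharpen: bool = False,
    per_image_params: Optional[Sequence[dict]] = None,
) -> list[np.ndarray]:
    """Apply ONE preprocessing parameter set to every image in a comparison.

    Uniform processing across a batch is a correctness requirement for fold
    changes, so per-image parameter overrides are refused unless identical.
    """
    if per_image_params is not None:
        distinct = {tuple(sorted(p.items())) for p in per_image_params}
        if len(distinct) > 1:
            raise ValueError(
                "preprocessing parameters differ across the batch; overlap "
                "fold changes require identical adjustment of every image"
            )
    return [preprocess_channel(ch, stretch=stretch, sharpen=sharpen) for ch in channels]


def batch_otsu_threshold(channels: Sequence[np.ndarray]) -> float:
    """One global Otsu threshold from the pooled histogram of a batch.

    Computing the threshold once on the pooled (typically control) batch and
    applying it to every image keeps the thresholding uniform.
    """
    pooled = np.concatenate([np.asarray(c, dtype=float).ravel() for c in channels])
    return float(threshold_otsu(pooled))


def binarize_and_filter(
    channel: np.ndarray,
    threshold: float | str = "otsu",
    min_size: int = DEFAULT_MIN_SIZE,
) -> LabeledMask:
    """Threshold a preprocessed channel and drop components under ``min_size``.

    Pixels with intensity >= threshold are foreground. Connected components
    (8-connected) with area strictly below ``min_size`` pixels are removed;
    a component of exactly ``min_size`` pixels survives. ``threshold`` may be
    a value in [0, 1] or ``"otsu"`` to compute it from this channel alone.
    """
    channel = np.asarray(channel, dtype=float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        thr = float(threshold_otsu(channel)) if channel.min() < channel.max() else 1.0
    else:
        thr = float(threshold)
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {thr}")
    mask = channel >= thr
    if min_size > 1:
        # max_size removes components of area <= max_size, so min_size - 1
        # implements "strictly below min_size removed; exactly min_size kept"
        mask = remove_small_objects(mask, max_size=min_size - 1, connectivity=CONNECTIVITY)
    n_objects = int(cc_label(mask, connectivity=CONNECTIVITY).max())
    return LabeledMask(
        mask=mask,
        n_objects=n_objects,
        provenance={
            "threshold": thr,
            "min_size": min_size,
            "connectivity": f"{4 * CONNECTIVITY}-connected",
        },
    )


def _as_mask(m: LabeledMask | np.ndarray) -> np.ndarray:
    return m.mask if isinstance(m, LabeledMask) else np.asarray(m, dtype=bool)


def overlap_pixels(
    mask_a: LabeledMask | np.ndarray,
    mask_b: LabeledMask | np.ndarray,
    sample_id: str = "",
    group: str = "",
    dilate: int = 0,
) -> OverlapMeasurement:
    """Count pixel coordinates foreground in both binarized channels.

    ``dilate`` optionally grows both masks by a disk of that radius before
    intersecting, the tolerance used when diffraction-limited signals are
    treated as touching.
    """
    a, b = _as_mask(mask_a), _as_mask(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if dilate > 0:
        selem = disk(dilate)
        a, b = dilation(a, selem), dilation(b, selem)
    return OverlapMeasurement(
        pixels_a=int(a.sum()),
        pixels_b=int(b.sum()),
        overlap_pixels=int(np.logical_and(a, b).sum()),
        sample_id=sample_id,
        group=group,
    )


def triple_overlap(
    mask_er: LabeledMask | np.ndarray,
    mask_mito: LabeledMask | np.ndarray,
    mask_protein: LabeledMask | np.ndarray,
    sample_id: str = "",
    group: str = "",
) -> OverlapMeasurement:
    """Count coordinates foreground in all three masks (ER ∧ mito ∧ protein)."""
    a, b, c = _as_mask(mask_er), _as_mask(mask_mito), _as_mask(mask_protein)
    if not (a.shape == b.shape == c.shape):
        raise ValueError(f"mask shapes differ: {a.shape}, {b.shape}, {c.shape}")
    return OverlapMeasurement(
        pixels_a=int(a.sum()),
        pixels_b=int(b.sum()),
        overlap_pixels=int((a & b & c).sum()),
        pixels_c=int(c.sum()),
        sample_id=sample_id,
        group=group,
    )


def overlap_index(
    measurements: Sequence[OverlapMeasurement],
    control_group: str,
) -> OverlapIndexResult:
    """Fold change of overlapping pixels over the control-group mean.

    Each sample's index is its ``overlap_pixels`` divided by the mean
    ``overlap_pixels`` of the control group, so the control group averages
    to 1 by construction. Group mean ± SEM are reported; the SEM of a
    singleton group is undefined and reported as ``None``.
    """
    controls = [m for m in measurements if m.group == control_group]
    if not controls:
        raise ValueError(f"control group {control_group!r} is empty")
    control_mean = float(np.mean([m.overlap_pixels for m in controls]))
    if control_mean <= 0:
        raise ValueError(
            "control-group mean overlap is zero; a fold change over zero is undefined"
        )
    indices = {m.sample_id: m.overlap_pixels / control_mean for m in measurements}
    groups = {m.sample_id: m.group for m in measurements}
    group_mean: dict[str, float] = {}
    group_sem: dict[str, Optional[float]] = {}
    for g in dict.fromkeys(groups.values()):
        vals = np.array([indices[s] for s, gg in groups.items() if gg == g])
        group_mean[g] = float(vals.mean())
        group_sem[g] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else None
    return OverlapIndexResult(indices, groups, control_group, control_mean, group_mean, group_sem)


def pearson_colocalization(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    roi: Optional[np.ndarray] = None,
) -> tuple[Optional[float], str]:
    """Pearson product-moment correlation of two raw intensity channels.

    Computed over the ROI pixels (whole image when ``roi`` is None) on
    unbinarized intensities. Returns ``(coefficient, reason)``; the
    coefficient is ``None`` with an explanatory reason when either channel
    has zero variance in the ROI or the ROI holds fewer than two pixels.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != a.shape:
            raise ValueError("roi shape must match the channels")
        a, b = a[roi], b[roi]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        return None, "fewer than 2 pixels in ROI"
    da, db = a - a.mean(), b - b.mean()
    va, vb = float(np.dot(da, da)), float(np.dot(db, db))
    if va == 0.0 or vb == 0.0:
        return None, "zero variance in at least one channel"
    return float(np.dot(da, db) / np.sqrt(va * vb)), "ok"
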
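"""Synthetic ground-truth generators for every assay the package quantifies.

Each generator is a pure function of its parameters and an explicit seed, and
returns both the simulated measurement (image, trace, plate, table) and the
ground truth it was rendered from, so every downstream statistic has an exact
recovery target without any external data.

Geometry choices favour analytic tractability over optical realism: ER
tubules are dilated random walks, mitochondria are straight "capsules"
(dilated line segments, i.e. stadium shapes) whose true length is the
Euclidean centerline length times the pixel size, and puncta are uniform
disks. No point-spread function or camera model is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .datatypes import AtpPlate, MultiChannelImage, TracePair


class ParameterError(ValueError):
    """A generator or analysis parameter is outside its documented range."""


class PlacementError(RuntimeError):
    """Requested objects could not be placed without overlap."""


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------


@dataclass
class ImageGroundTruth:
    """True organelle masks and puncta behind one simulated two-organelle cell.

    ``contact_mask`` follows the dilation rule
    ``dilate(er, d) & dilate(mito, d)``: diffraction-limited signals are
    treated as touching when they come within ``d`` pixels of each other.
    """

    er_mask: np.ndarray
    mito_mask: np.ndarray
    contact_mask: np.ndarray
    protein_puncta: list = field(default_factory=list)  # (row, col, radius, at_contact)
    pixel_size: float = 0.05
    contact_dilation: int = 1
    seed: int = 0


@dataclass
class MitoGroundTruth:
    """Capsule centerlines and true physical lengths for one simulated field."""

    capsules: list  # (r0, c0, r1, c1, width_px, true_length_um)
    pixel_size: float = 0.1
    seed: int = 0

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([c[5] for c in self.capsules], dtype=float)


@dataclass
class PlateGroundTruth:
    """True pathway fractions behind one simulated ATP luminescence plate."""

    glucose_dependence: float
    mitochondrial_dependence: float
    baseline_luminescence: float = 1000.0
    cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("glucose_dependence", "mitochondrial_dependence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.cv < 0:
            raise ParameterError(f"cv must be non-negative, got {self.cv}")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


@dataclass
class NoiseModel:
    """Additive Gaussian and optional Poisson (shot) noise for rendered images."""

    gaussian_sd: float = 0.0
    poisson: bool = False
    poisson_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ParameterError(f"gaussian_sd must be non-negative, got {self.gaussian_sd}")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image.astype(float)
        if self.poisson:
            out = rng.poisson(np.clip(out, 0, None) * self.poisson_scale) / self.poisson_scale
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# drawing helpers
# ---------------------------------------------------------------------------


def _check_shape(shape: tuple[int, int]) -> None:
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise ParameterError(f"image shape must be two positive integers, got {shape}")
    if shape[0] < 64 or shape[1] < 64:
        raise ParameterError(f"image dimensions must be >= 64x64, got {shape}")


def _random_walk_mask(shape, n_steps, width_px, rng) -> np.ndarray:
    """One ER tubule: an 8-direction random walk dilated to a band."""
    mask = np.zeros(shape, dtype=bool)
    r = rng.integers(width_px, shape[0] - width_px)
    c = rng.integers(width_px, shape[1] - width_px)
    steps = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)])
    drift = steps[rng.integers(8)]
    for _ in range(n_steps):
        mask[r, c] = True
        # persistent walk: mostly keep heading, occasionally turn
        if rng.random() < 0.2:
            drift = steps[rng.integers(8)]
        r = int(np.clip(r + drift[0], 1, shape[0] - 2))
        c = int(np.clip(c + drift[1], 1, shape[1] - 2))
    if width_px > 1:
        mask = dilation(mask, disk(width_px / 2))
    return mask


def _capsule_mask(shape, r0, c0, r1, c1, width_px) -> np.ndarray:
    """Stadium shape: a line segment dilated by a disk of radius width/2."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    mask[rr[keep], cc[keep]] = True
    return dilation(mask, disk(width_px / 2))


def _segment_endpoints(mid_r, mid_c, length_px, theta):
    dr = 0.5 * length_px * math.sin(theta)
    dc = 0.5 * length_px * math.cos(theta)
    return mid_r - dr, mid_c - dc, mid_r + dr, mid_c + dc


# ---------------------------------------------------------------------------
# two-organelle cell images (contact / overlap ground truth)
# ---------------------------------------------------------------------------


def generate_cell_image(
    shape: tuple[int, int] = (256, 256),
    n_tubules: int = 6,
    tubule_steps: int = 300,
    tubule_width_px: int = 3,
    n_contact_capsules: int = 8,
    n_free_capsules: int = 6,
    capsule_length_px: tuple[float, float] = (15, 35),
    capsule_width_px: int = 5,
    n_puncta: int = 20,
    puncta_radius_px: float = 2.0,
    puncta_contact_fraction: float = 0.7,
    contact_dilation: int = 1,
    intensities: dict | None = None,
    noise_model: NoiseModel | None = None,
    pixel_size: float = 0.05,
    sample_id: str = "",
    group: str = "",
    seed: int = 0,
) -> tuple[MultiChannelImage, ImageGroundTruth]:
    """Render a 3-channel (ER, mitochondria, protein) cell with known contacts.

    ER tubules are dilated random walks. ``n_contact_capsules`` mitochondria
    are centered on ER foreground so each crossing contributes contact area;
    the expected total contact area therefore scales linearly with that
    count, which is what makes group-ratio recovery testable.
    ``n_free_capsules`` mitochondria are placed away from the ER. A fraction
    of protein puncta is seeded inside the realized contact mask to emulate
    contact-site enrichment.

    Returns the noisy image and the exact ground truth (noiseless foreground
    equals ``mask * intensity``).
    """
    _check_shape(shape)
    for name, v in [
        ("n_tubules", n_tubules),
        ("n_contact_capsules", n_contact_capsules),
        ("n_free_capsules", n_free_capsules),
        ("n_puncta", n_puncta),
    ]:
        if v < 0:
            raise ParameterError(f"{name} must be >= 0, got {v}")
    if contact_dilation < 0:
        raise ParameterError("contact_dilation must be >= 0")
    noise_model = noise_model or NoiseModel()
    intensities = intensities or {"er": 0.8, "mito": 0.9, "protein": 1.0}
    rng = np.random.default_rng(seed)

    er = np.zeros(shape, dtype=bool)
    for _ in range(n_tubules):
        er |= _random_walk_mask(shape, tubule_steps, tubule_width_px, rng)

    mito = np.zeros(shape, dtype=bool)
    er_coords = np.argwhere(er)
    for _ in range(n_contact_capsules):
        if er_coords.size == 0:
            break
        mid = er_coords[rng.integers(len(er_coords))]
        length = rng.uniform(*capsule_length_px)
        theta = rng.uniform(0, math.pi)
        mito |= _capsule_mask(shape, *_segment_endpoints(mid[0], mid[1], length, theta), capsule_width_px)
    margin = int(max(capsule_length_px) / 2 + capsule_width_px)
    for _ in range(n_free_capsules):
        for _attempt in range(200):
            mid_r = rng.uniform(margin, shape[0] - margin)
            mid_c = rng.uniform(margin, shape[1] - margin)
            length = rng.uniform(*capsule_length_px)
            theta = rng.uniform(0, math.pi)
            cand = _capsule_mask(shape, *_segment_endpoints(mid_r, mid_c, length, theta), capsule_width_px)
            # free capsules must stay clear of the (dilated) ER so they add
            # mitochondrial area without adding contact area
            if not (dilation(cand, disk(contact_dilation + 1)) & er).any():
                mito |= cand
                break

    if contact_dilation > 0:
        selem = disk(contact_dilation)
        contact = dilation(er, selem) & dilation(mito, selem)
    else:
        contact = er & mito

    puncta: list[tuple[int, int, float, bool]] = []
    protein = np.zeros(shape, dtype=bool)
    contact_coords = np.argwhere(contact)
    n_at_contact = int(round(n_puncta * puncta_contact_fraction))
    for i in range(n_puncta):
        at_contact = i < n_at_contact and contact_coords.size > 0
        if at_contact:
            r, c = contact_coords[rng.integers(len(contact_coords))]
        else:
            r = rng.integers(5, shape[0] - 5)
            c = rng.integers(5, shape[1] - 5)
            at_contact = False
        rr, cc = draw_disk((r, c), puncta_radius_px, shape=shape)
        protein[rr, cc] = True
        puncta.append((int(r), int(c), float(puncta_radius_px), bool(at_contact)))

    channels = {
        "er": noise_model.apply(er * intensities["er"], rng),
        "mito": noise_model.apply(mito * intensities["mito"], rng),
        "protein": noise_model.apply(protein * intensities["protein"], rng),
    }
    image = MultiChannelImage(channels, pixel_size=pixel_size, sample_id=sample_id, group=group)
    truth = ImageGroundTruth(er, mito, contact, puncta, pixel_size, contact_dilation, seed)
    return image, truth


# ---------------------------------------------------------------------------
# capsule fields for length measurement
# ---------------------------------------------------------------------------


def generate_capsule_image(
    n_capsules: int = 30,
    length_um: tuple[float, float] | np.ndarray = (1.0, 8.0),
    width_px: int = 5,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.1,
    noise_model: NoiseModel | None = None,
    intensity: float = 1.0,
    max_attempts: int = 500,
    sample_id: str = "",
    group: str = "",
    seed: int = 0,
) -> tuple[MultiChannelImage, MitoGroundTruth]:
    """Render non-overlapping straight capsules with known physical lengths.

    ``length_um`` is either a ``(low, high)`` uniform sampling range or an
    explicit array of lengths. Capsules are rejected-sampled until they do
    not touch previously placed ones (one-pixel separation); failure to place
    one within ``max_attempts`` raises :class:`PlacementError` naming how
    many were achieved.
    """
    _check_shape(shape)
    if width_px < 3:
        raise ParameterError(f"width_px must be >= 3, got {width_px}")
    if n_capsules < 0:
        raise ParameterError("n_capsules must be >= 0")
    noise_model = noise_model or NoiseModel()
    rng = np.random.default_rng(seed)

    if isinstance(length_um, tuple):
        lengths = rng.uniform(length_um[0], length_um[1], size=n_capsules)
    else:
        lengths = np.asarray(length_um, dtype=float)
        if len(lengths) != n_capsules:
            raise ParameterError("explicit length list must match n_capsules")
    if np.any(lengths <= 0):
        raise ParameterError("capsule lengths must be > 0")

    occupied = np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    capsules = []
    for i, length in enumerate(lengths):
        length_px = length / pixel_size
        margin = length_px / 2 + width_px
        placed = False
        for _ in range(max_attempts):
            mid_r = rng.uniform(margin, shape[0] - margin)
            mid_c = rng.uniform(margin, shape[1] - margin)
            theta = rng.uniform(0, math.pi)
            r0, c0, r1, c1 = _segment_endpoints(mid_r, mid_c, length_px, theta)
            cand = _capsule_mask(shape, r0, c0, r1, c1, width_px)
            if not (dilation(cand, disk(1)) & occupied).any():
                occupied |= dilation(cand, disk(1))
                mask |= cand
                # endpoint rounding is what the renderer actually drew, so the
                # recorded true length is measured on the rounded centerline
                rr0, cc0 = round(r0), round(c0)
                rr1, cc1 = round(r1), round(c1)
                true_len = math.hypot(rr1 - rr0, cc1 - cc0) * pixel_size
                capsules.append((rr0, cc0, rr1, cc1, width_px, true_len))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"placed only {i} of {n_capsules} capsules without overlap "
                f"after {max_attempts} attempts each"
            )

    channel = noise_model.apply(mask * intensity, rng)
    image = MultiChannelImage({"mito": channel}, pixel_size=pixel_size, sample_id=sample_id, group=group)
    return image, MitoGroundTruth(capsules, pixel_size, seed)


# ---------------------------------------------------------------------------
# tandem-fluorophore reporter images
# ---------------------------------------------------------------------------


def round_half_away_from_zero(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def generate_reporter_image(
    n_puncta: int = 30,
    red_only_fraction: float = 0.3,
    shape: tuple[int, int] = (256, 256),
    puncta_radius_px: float = 3.0,
    red_intensity: float = 1.0,
    green_intensity: float = 0.9,
    background: float = 0.05,
    noise_model: NoiseModel | None = None,
    min_separation_px: float = 10.0,
    pixel_size: float = 0.1,
    sample_id: str = "",
    group: str = "",
    seed: int = 0,
) -> tuple[MultiChannelImage, list[tuple[int, int, bool]]]:
    """Render a two-channel (red, green) tandem-reporter cell.

    Exactly ``round(n_puncta * red_only_fraction)`` puncta (half away from
    zero) are "red-only" — green stays at background, emulating EGFP
    quenching in acidic vesicles — and the rest carry both fluorophores.
    Returns the image and per-punctum truth ``(row, col, red_only)``.
    """
    if n_puncta < 0:
        raise ParameterError("n_puncta must be >= 0")
    if not 0.0 <= red_only_fraction <= 1.0:
        raise ParameterError(f"red_only_fraction must be in [0, 1], got {red_only_fraction}")
    _check_shape(shape)
    noise_model = noise_model or NoiseModel()
    rng = np.random.default_rng(seed)

    n_red_only = round_half_away_from_zero(n_puncta * red_only_fraction)
    red = np.full(shape, background, dtype=float)
    green = np.full(shape, background, dtype=float)

    centers: list[tuple[int, int]] = []
    margin = int(puncta_radius_px + 2)
    for _ in range(n_puncta):
        for _attempt in range(1000):
            r = int(rng.integers(margin, shape[0] - margin))
            c = int(rng.integers(margin, shape[1] - margin))
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation_px**2 for pr, pc in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError(f"placed only {len(centers)} of {n_puncta} puncta")

    order = rng.permutation(n_puncta)
    truth: list[tuple[int, int, bool]] = [None] * n_puncta  # type: ignore[list-item]
    for rank, idx in enumerate(order):
        r, c = centers[idx]
        red_only = rank < n_red_only
        rr, cc = draw_disk((r, c), puncta_radius_px, shape=shape)
        red[rr, cc] = red_intensity
        if not red_only:
            green[rr, cc] = green_intensity
        truth[idx] = (r, c, red_only)

    channels = {
        "red": noise_model.apply(red, rng),
        "green": noise_model.apply(green, rng),
    }
    image = MultiChannelImage(channels, pixel_size=pixel_size, sample_id=sample_id, group=group)
    return image, truth


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------


def generate_calcium_traces(
    direction: str = "efflux",
    rate_constant: float = 0.01,
    amplitude: float = 100.0,
    baseline: float | None = None,
    reference_level: float = 50.0,
    bleach_rate: float = 0.0,
    n_timepoints: int = 120,
    dt: float = 5.0,
    noise_sd: float = 0.0,
    sample_id: str = "",
    group: str = "",
    seed: int = 0,
) -> TracePair:
    """Simulate an organelle calcium indicator with a stable reference channel.

    Efflux (e.g. ER store depletion after histamine):
    ``I(t) = baseline + A * exp(-k t)`` with baseline default 0.
    Influx (mitochondrial uptake): ``I(t) = baseline + A * (1 - exp(-k t))``
    with baseline default ``A`` so the trace starts above zero. When
    ``bleach_rate > 0`` both channels decay by the shared factor
    ``exp(-bleach_rate * t)``, which the reference normalization must cancel.
    """
    if direction not in ("efflux", "influx"):
        raise ParameterError(f"direction must be 'efflux' or 'influx', got {direction!r}")
    if rate_constant < 0:
        raise ParameterError(f"rate constant must be >= 0, got {rate_constant}")
    if n_timepoints < 2:
        raise ParameterError("n_timepoints must be >= 2")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    t = np.arange(n_timepoints) * dt
    if direction == "efflux":
        base = 0.0 if baseline is None else baseline
        indicator = base + amplitude * np.exp(-rate_constant * t)
    else:
        base = amplitude if baseline is None else baseline
        indicator = base + amplitude * (1.0 - np.exp(-rate_constant * t))
    reference = np.full_like(t, float(reference_level))
    if bleach_rate > 0:
        decay = np.exp(-bleach_rate * t)
        indicator = indicator * decay
        reference = reference * decay
    if noise_sd > 0:
        indicator = indicator + rng.normal(0, noise_sd, size=t.shape)
        reference = reference + rng.normal(0, noise_sd, size=t.shape)
    return TracePair(t, indicator, reference, sample_id=sample_id, group=group)


# ---------------------------------------------------------------------------
# ATP luminescence plates
# ---------------------------------------------------------------------------


def generate_atp_plate(
    truth: PlateGroundTruth, sample_id: str = "", group: str = ""
) -> AtpPlate:
    """Simulate replicate luminescence for the four-arm inhibitor design.

    Condition means derive from the true pathway fractions: blocking glucose
    metabolism (DG) removes the glucose-dependent fraction, blocking ATP
    synthase (OA) removes the mitochondria-dependent fraction, and the
    combined arm follows the independent-action product
    ``B * (1 - g) * (1 - m)`` clipped at zero. Replicates carry multiplicative
    lognormal noise with the stated coefficient of variation (mean-preserving:
    ``sigma^2 = ln(1 + cv^2)``, ``mu = -sigma^2 / 2``).
    """
    rng = np.random.default_rng(truth.seed)
    b = truth.baseline_luminescence
    g, m = truth.glucose_dependence, truth.mitochondrial_dependence
    means = {
        "control": b,
        "DG": b * (1.0 - g),
        "OA": b * (1.0 - m),
        "DGOA": max(0.0, b * (1.0 - g) * (1.0 - m)),
    }
    if truth.cv > 0:
        sigma = math.sqrt(math.log(1.0 + truth.cv**2))
        factors = {
            cond: rng.lognormal(-sigma**2 / 2.0, sigma, size=truth.n_replicates)
            for cond in means
        }
    else:
        factors = {cond: np.ones(truth.n_replicates) for cond in means}
    replicates = {cond: means[cond] * factors[cond] for cond in means}
    return AtpPlate(sample_id=sample_id, group=group, replicates=replicates)


# ---------------------------------------------------------------------------
# gene statistics tables
# ---------------------------------------------------------------------------


def generate_gene_table(
    n_null: int = 1000,
    n_up: int = 25,
    n_down: int = 15,
    effect_log2fc: float = 2.0,
    n_mito_genes: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Simulate a per-gene statistics table with spiked regulated genes.

    Null genes get log2 fold changes near zero (clipped inside the cutoff)
    and uniform p-values; spiked genes get ``|log2FC| >= effect_log2fc`` and
    p-values well below 0.01, so a threshold filter at the standard cutoffs
    recovers the truth labels exactly. A mitochondrial gene list is sampled
    from the whole gene universe.

    Returns ``(table, mito_gene_list, truth_labels)`` where the table has
    columns ``gene``, ``log2fc``, ``pvalue`` and truth labels are
    ``null`` / ``up`` / ``down`` indexed by gene.
    """
    for name, v in [("n_null", n_null), ("n_up", n_up), ("n_down", n_down),
                    ("n_mito_genes", n_mito_genes)]:
        if v < 0:
            raise ParameterError(f"{name} must be >= 0, got {v}")
    total = n_null + n_up + n_down
    if n_mito_genes > total:
        raise ParameterError(
            f"n_mito_genes ({n_mito_genes}) exceeds total genes ({total})"
        )
    rng = np.random.default_rng(seed)

    genes = [f"GENE{i:05d}" for i in range(total)]
    labels = np.array(["null"] * n_null + ["up"] * n_up + ["down"] * n_down)

    lfc = np.empty(total)
    pval = np.empty(total)
    lfc[:n_null] = np.clip(rng.normal(0.0, 0.4, n_null), -1.5, 1.5)
    pval[:n_null] = rng.uniform(np.finfo(float).tiny, 1.0, n_null)
    n_spiked = n_up + n_down
    magnitudes = effect_log2fc + np.abs(rng.normal(0.0, 0.5, n_spiked))
    signs = np.array([1.0] * n_up + [-1.0] * n_down)
    lfc[n_null:] = signs * magnitudes
    pval[n_null:] = 10.0 ** rng.uniform(-8, -3, n_spiked)

    order = rng.permutation(total)
    table = pd.DataFrame(
        {"gene": np.array(genes)[order], "log2fc": lfc[order], "pvalue": pval[order]}
    )
    truth = pd.Series(labels[order], index=table["gene"].to_numpy(), name="truth")
    mito_list = list(rng.choice(genes, size=n_mito_genes, replace=False))
    return table, mito_list, truth


# ---------------------------------------------------------------------------
# flow-cytometry event populations
# ---------------------------------------------------------------------------


def generate_flow_populations(
    n_events: int,
    log_mean: dict[str, float],
    log_sd: float | dict[str, float] = 0.5,
    sample_id: str = "",
    group: str = "",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-event lognormal channel intensities (one row per event).

    ``log_mean`` maps channel name to the natural-log mean; ``log_sd`` is a
    shared or per-channel natural-log standard deviation. The population MFI
    has the closed form ``exp(mu + sigma^2 / 2)``.
    """
    if n_events < 1:
        raise ParameterError(f"n_events must be >= 1, got {n_events}")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for channel, mu in log_mean.items():
        sd = log_sd[channel] if isinstance(log_sd, dict) else log_sd
        if sd < 0:
            raise ParameterError(f"log_sd for {channel!r} must be >= 0, got {sd}")
        data[channel] = rng.lognormal(mu, sd, size=n_events)
    frame = pd.DataFrame(data)
    frame.insert(0, "sample_id", sample_id)
    frame.insert(1, "group", group)
    return frame
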
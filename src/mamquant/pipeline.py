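"""End-to-end orchestration: simulate → quantify → summarize → report.

A run is described by a :class:`RunConfig` (loadable from YAML); requested
stages execute in dependency order, every stage writes its tabular output
under the run directory, and a machine-readable JSON run log records the
full parameter set, seed and package version so identical config + seed
reproduce identical outputs. The group comparison used throughout is the
unpaired two-tailed Welch t-test on per-sample summary values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__, io
from .bioenergetics import metabolic_profile, profiles_frame, total_atp_comparison
from .colocalization import (
    batch_otsu_threshold,
    binarize_and_filter,
    overlap_index,
    overlap_pixels,
    preprocess_channel,
)
from .morphometry import measure_lengths, summarize_morphology
from .synthetic import (
    NoiseModel,
    PlateGroundTruth,
    generate_atp_plate,
    generate_capsule_image,
    generate_cell_image,
)

logger = logging.getLogger("mamquant")

EXIT_INPUT_ERROR = 2
EXIT_DEGENERACY_ERROR = 3

STAGES = ("simulate", "coloc", "morpho", "atp")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; YAML keys mirror the field names."""

    out_dir: str = "mamquant_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    control_group: str = "control"
    stress_group: str = "stress"
    n_images_per_group: int = 4
    image_shape: tuple = (256, 256)
    stress_contact_multiplier: int = 2
    noise_sd: float = 0.05
    stretch: tuple = (1.0, 99.5)
    min_size: int = 10
    dilate: int = 0
    n_capsules: int = 20
    pixel_size_um: float = 0.1
    n_plates_per_group: int = 3
    plate_truth: dict = field(
        default_factory=lambda: {
            "control": {"glucose_dependence": 0.4, "mitochondrial_dependence": 0.6},
            "stress": {"glucose_dependence": 0.55, "mitochondrial_dependence": 0.35},
        }
    )
    plate_cv: float = 0.05
    plate_replicates: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class GroupComparison:
    """Welch two-sample comparison of per-sample values between two groups."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    fold_change: float  # mean_b / mean_a (group a is the control/reference)
    degenerate_variance: bool = False
    test: str = "welch_two_tailed"


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Unpaired two-tailed Welch t-test plus means ± SEM and fold change.

    ``values_a`` is the control/reference group (fold change = mean_b /
    mean_a). Zero variance in both groups is reported explicitly via
    ``degenerate_variance`` (t undefined → 0 or inf depending on means).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 for a two-sample comparison")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate:
        t_stat = 0.0 if np.isclose(a.mean(), b.mean()) else np.inf
        p_value = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        res = stats.ttest_ind(b, a, equal_var=False)
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        n_a=len(a),
        n_b=len(b),
        t_statistic=t_stat,
        p_value=p_value,
        fold_change=float(b.mean() / a.mean()) if a.mean() != 0 else np.inf,
        degenerate_variance=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _simulate(cfg: RunConfig, rng_seed: int):
    """Generate the synthetic bundle: cell images, capsule field, plates."""
    images = []
    seed = rng_seed
    for group, mult in ((cfg.control_group, 1), (cfg.stress_group, cfg.stress_contact_multiplier)):
        for i in range(cfg.n_images_per_group):
            seed += 1
            img, truth = generate_cell_image(
                shape=tuple(cfg.image_shape),
                n_contact_capsules=8 * mult,
                n_free_capsules=6,
                noise_model=NoiseModel(gaussian_sd=cfg.noise_sd),
                sample_id=f"{group}_{i:02d}",
                group=group,
                seed=seed,
            )
            images.append((img, truth))
    capsule_img, capsule_truth = generate_capsule_image(
        n_capsules=cfg.n_capsules,
        pixel_size=cfg.pixel_size_um,
        sample_id="capsules_00",
        seed=rng_seed + 1000,
    )
    plates = []
    pseed = rng_seed + 2000
    for group, truth_params in cfg.plate_truth.items():
        for i in range(cfg.n_plates_per_group):
            pseed += 1
            truth = PlateGroundTruth(
                **truth_params,
                cv=cfg.plate_cv,
                n_replicates=cfg.plate_replicates,
                seed=pseed,
            )
            plates.append(generate_atp_plate(truth, sample_id=f"{group}_p{i:02d}", group=group))
    return images, (capsule_img, capsule_truth), plates


def _run_coloc(cfg: RunConfig, images, out_dir: Path) -> pd.DataFrame:
    adjusted = {
        img.sample_id: {
            ch: preprocess_channel(img.channels[ch], stretch=tuple(cfg.stretch))
            for ch in ("er", "mito")
        }
        for img, _ in images
    }
    control_channels = [
        v[ch]
        for (img, _), v in zip(images, adjusted.values())
        if img.group == cfg.control_group
        for ch in ("er", "mito")
    ]
    threshold = batch_otsu_threshold(control_channels)
    measurements = []
    for img, _ in images:
        masks = {
            ch: binarize_and_filter(adjusted[img.sample_id][ch], threshold, cfg.min_size)
            for ch in ("er", "mito")
        }
        measurements.append(
            overlap_pixels(masks["er"], masks["mito"], img.sample_id, img.group, dilate=cfg.dilate)
        )
    result = overlap_index(measurements, cfg.control_group)
    per_sample = pd.DataFrame(
        {
            "sample_id": list(result.indices),
            "group": [result.groups[s] for s in result.indices],
            "overlap_pixels": [m.overlap_pixels for m in measurements],
            "overlap_index": list(result.indices.values()),
        }
    )
    per_sample.to_csv(out_dir / "coloc_per_sample.csv", index=False)
    summary = pd.DataFrame(
        {
            "group": list(result.group_mean),
            "mean_index": list(result.group_mean.values()),
            "sem_index": [result.group_sem[g] for g in result.group_mean],
        }
    )
    summary.to_csv(out_dir / "coloc_summary.csv", index=False)
    return per_sample


def _run_morpho(cfg: RunConfig, capsule_bundle, out_dir: Path) -> pd.DataFrame:
    img, _truth = capsule_bundle
    objects = measure_lengths(
        img.channels["mito"], img.pixel_size, min_size=cfg.min_size,
        sample_id=img.sample_id, group="capsules",
    )
    summaries = summarize_morphology(objects)
    per_object = pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in objects],
            "object_id": [o.object_id for o in objects],
            "length_um": [o.length_um for o in objects],
            "category": [o.category for o in objects],
        }
    )
    per_object.to_csv(out_dir / "morpho_per_object.csv", index=False)
    rows = []
    for g, s in summaries.items():
        row = {"group": g, "n_objects": s.n_objects, "median_um": s.median_um}
        if s.fractions:
            row.update({f"frac_{cat}": v for cat, v in s.fractions.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "morpho_summary.csv", index=False)
    return per_object


def _run_atp(cfg: RunConfig, plates, out_dir: Path) -> pd.DataFrame:
    profiles = [metabolic_profile(p) for p in plates]
    frame = profiles_frame(profiles)
    frame.to_csv(out_dir / "atp_profiles.csv", index=False)
    total = total_atp_comparison(plates, reference_group=cfg.control_group)
    total.to_csv(out_dir / "atp_total.csv")
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write outputs plus a JSON run log.

    Returns a dict mapping stage name to its primary output path. A stage
    failure aborts the run with an error naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; expected subset of {STAGES}")
    ordered = [s for s in STAGES if s in config.stages]
    outputs: dict[str, str] = {}
    images = capsule_bundle = plates = None
    for stage in ordered:
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                images, capsule_bundle, plates = _simulate(config, config.seed)
                io.write_plates(out_dir / "simulated_plates.csv", plates)
                outputs["simulate"] = str(out_dir / "simulated_plates.csv")
            elif stage == "coloc":
                if images is None:
                    raise ValueError("coloc requires the simulate stage")
                _run_coloc(config, images, out_dir)
                outputs["coloc"] = str(out_dir / "coloc_per_sample.csv")
            elif stage == "morpho":
                if capsule_bundle is None:
                    raise ValueError("morpho requires the simulate stage")
                _run_morpho(config, capsule_bundle, out_dir)
                outputs["morpho"] = str(out_dir / "morpho_per_object.csv")
            elif stage == "atp":
                if plates is None:
                    raise ValueError("atp requires the simulate stage")
                _run_atp(config, plates, out_dir)
                outputs["atp"] = str(out_dir / "atp_profiles.csv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages_run": ordered,
        "outputs": outputs,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return outputs
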
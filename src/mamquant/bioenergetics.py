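"""Fractional ATP bioenergetics profiling from inhibitor luminescence plates.

ATP production is partitioned with the four-arm inhibitor design: 2-deoxy-
D-glucose (DG) blocks glucose metabolism, oligomycin A (OA) blocks the
mitochondrial ATP synthase, and their combination (DGOA) blocks both. The
four reported quantities come from relative decreases of condition-mean
luminescence against the vehicle control:

    glucose dependence        = (ctrl - DG) / ctrl
    FAO/AAO capacity          = 1 - glucose dependence
    mitochondrial dependence  = (ctrl - OA) / ctrl
    glycolytic capacity       = 1 - mitochondrial dependence

so the two complementary pairs each sum to one exactly, and the profile is
invariant to rescaling all luminescence values. The combined DGOA arm is
loaded and reported but does not enter the default formulas; an optional
mode subtracts its mean from every condition first (treating it as the
non-glycolytic, non-mitochondrial background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AtpPlate

FRACTION_NAMES = (
    "glucose_dependence",
    "faa_aao_capacity",
    "mitochondrial_dependence",
    "glycolytic_capacity",
)


@dataclass
class MetabolicProfile:
    """The four pathway fractions for one sample, with % and range flags.

    Fractions outside [0, 1] (possible with noisy plates when an inhibitor
    arm exceeds the control) are reported as computed and flagged in
    ``out_of_range`` rather than silently truncated.
    """

    sample_id: str
    group: str
    glucose_dependence: float
    faa_aao_capacity: float
    mitochondrial_dependence: float
    glycolytic_capacity: float
    baseline_mode: str = "none"
    out_of_range: list = field(default_factory=list)

    @property
    def percentages(self) -> dict[str, float]:
        return {name: 100.0 * getattr(self, name) for name in FRACTION_NAMES}

    def as_dict(self) -> dict:
        row = {"sample_id": self.sample_id, "group": self.group}
        for name in FRACTION_NAMES:
            row[name] = getattr(self, name)
            row[f"{name}_pct"] = 100.0 * getattr(self, name)
        row["out_of_range"] = ";".join(self.out_of_range)
        return row


def metabolic_profile(
    plate: AtpPlate,
    baseline: str = "none",
    per_replicate: bool = False,
) -> MetabolicProfile:
    """Compute the four pathway fractions from one sample's plate.

    ``baseline="dgoa"`` subtracts the combined-arm mean from every condition
    mean before forming the ratios. ``per_replicate=True`` averages
    replicate-wise ratios instead of taking ratios of condition means (the
    default, matching ratios of ATP levels).
    """
    if baseline not in ("none", "dgoa"):
        raise ValueError(f"baseline must be 'none' or 'dgoa', got {baseline!r}")
    needed = {"control", "DG", "OA"} | ({"DGOA"} if baseline == "dgoa" else set())
    missing = needed - set(plate.replicates)
    if missing:
        raise ValueError(f"plate {plate.sample_id!r} lacks conditions: {sorted(missing)}")

    offset = plate.condition_mean("DGOA") if baseline == "dgoa" else 0.0

    def rel_decrease(cond: str) -> float:
        if per_replicate:
            ctrl = plate.replicates["control"] - offset
            if np.any(ctrl <= 0):
                raise ValueError("non-positive control replicate after baseline subtraction")
            vals = plate.replicates[cond] - offset
            n = min(len(ctrl), len(vals))
            return float(np.mean(1.0 - vals[:n] / ctrl[:n]))
        ctrl = plate.condition_mean("control") - offset
        if ctrl <= 0:
            raise ValueError(
                f"control mean is not positive (after baseline subtraction) for "
                f"plate {plate.sample_id!r}; fractions undefined"
            )
        return 1.0 - (plate.condition_mean(cond) - offset) / ctrl

    g = rel_decrease("DG")
    m = rel_decrease("OA")
    profile = MetabolicProfile(
        sample_id=plate.sample_id,
        group=plate.group,
        glucose_dependence=g,
        faa_aao_capacity=1.0 - g,
        mitochondrial_dependence=m,
        glycolytic_capacity=1.0 - m,
        baseline_mode=baseline,
    )
    profile.out_of_range = [
        name for name in FRACTION_NAMES if not 0.0 <= getattr(profile, name) <= 1.0
    ]
    return profile


def total_atp_comparison(
    plates: Sequence[AtpPlate],
    reference_group: str,
    condition: str = "control",
) -> pd.DataFrame:
    """Group-level total ATP (RLu): mean ± SEM and fold change vs a reference.

    Pools each plate's mean luminescence in ``condition`` per group and
    reports group mean, SEM (NaN for singleton groups), n, and fold change
    over the reference-group mean (1 for the reference itself). A Welch
    two-sample p-value against the reference group is included where both
    groups have n >= 2.
    """
    per_plate = pd.DataFrame(
        {
            "group": [p.group for p in plates],
            "rlu": [p.condition_mean(condition) for p in plates],
        }
    )
    if reference_group not in set(per_plate["group"]):
        raise ValueError(f"reference group {reference_group!r} has no plates")
    ref_values = per_plate.loc[per_plate["group"] == reference_group, "rlu"].to_numpy()
    ref_mean = ref_values.mean()
    rows = []
    for g, vals in per_plate.groupby("group")["rlu"]:
        v = vals.to_numpy()
        sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
        if g != reference_group and len(v) > 1 and len(ref_values) > 1:
            pval = float(stats.ttest_ind(v, ref_values, equal_var=False).pvalue)
        else:
            pval = np.nan
        rows.append(
            {
                "group": g,
                "n": len(v),
                "mean_rlu": v.mean(),
                "sem_rlu": sem,
                "fold_change": v.mean() / ref_mean,
                "p_value_vs_reference": pval,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def profiles_frame(profiles: Sequence[MetabolicProfile]) -> pd.DataFrame:
    """Tabulate profiles (fractions and percentages) for CSV export."""
    return pd.DataFrame([p.as_dict() for p in profiles])
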
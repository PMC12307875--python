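"""Reference-normalized calcium traces and flow-cytometry summaries.

ΔF/F0 is computed on the per-timepoint ratio of indicator to reference
channel, R(t) = indicator(t) / reference(t), so shared photobleaching or
focus drift cancels: dff0(t) = (R(t) - R(0)) / R(0), which is zero at t = 0
by construction. Flow summaries reduce per-event intensity tables to
arithmetic mean fluorescence intensities (MFI), the potential-to-mass
TMRM/MitoTracker-Green ratio, and fold changes over the control group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import TracePair


@dataclass
class NormalizedTrace:
    """ΔF/F0 series on the trace's own timebase; dff0[0] == 0 exactly."""

    time: np.ndarray
    dff0: np.ndarray
    sample_id: str = ""
    group: str = ""


@dataclass
class FlowSummary:
    """Per-sample MFIs, TMRM/MTG ratio and fold changes vs the control mean."""

    mfi: pd.DataFrame              # rows: sample_id; columns: channels (+ group)
    ratio: pd.Series               # TMRM/MTG per sample (may be empty)
    fold_change: pd.DataFrame      # per-channel fold change vs control mean
    control_group: str = ""


def dff0(pair: TracePair) -> NormalizedTrace:
    """Reference-normalized ΔF/F0 of one indicator/reference trace pair.

    Raises with the offending timepoint when the reference is zero anywhere
    or the initial ratio R(0) is not positive (the fold change would be
    undefined).
    """
    zero = np.flatnonzero(pair.reference <= 0)
    if zero.size:
        raise ValueError(
            f"reference channel is <= 0 at timepoint index {zero[0]} "
            f"(t = {pair.time[zero[0]]}); ratio undefined"
        )
    ratio = pair.indicator / pair.reference
    if ratio[0] <= 0:
        raise ValueError("initial ratio R(0) <= 0 at timepoint index 0; ΔF/F0 undefined")
    values = (ratio - ratio[0]) / ratio[0]
    values[0] = 0.0  # exact by definition
    return NormalizedTrace(pair.time.copy(), values, pair.sample_id, pair.group)


def summarize_traces(traces: Sequence[NormalizedTrace]) -> pd.DataFrame:
    """Pointwise mean ± SEM across traces sharing one timebase.

    Returns a frame with columns ``time``, ``mean``, ``sem``, ``n``. SEM is
    NaN when only one trace is given.
    """
    if not traces:
        raise ValueError("no traces to summarize")
    t0 = traces[0].time
    for tr in traces[1:]:
        if len(tr.time) != len(t0) or not np.allclose(tr.time, t0):
            raise ValueError("traces do not share one timebase")
    stack = np.vstack([tr.dff0 for tr in traces])
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(t0), np.nan)
    return pd.DataFrame({"time": t0, "mean": stack.mean(axis=0), "sem": sem, "n": n})


def fit_rate_constant(trace: NormalizedTrace) -> float:
    """Recover an efflux rate constant by log-linear regression on 1 + ΔF/F0.

    For an exponential efflux trace with constant reference,
    1 + dff0(t) = exp(-k t), so -slope of ln(1 + dff0) against time is k.
    Timepoints where 1 + dff0 <= 0 are excluded.
    """
    y = 1.0 + trace.dff0
    keep = y > 0
    if keep.sum() < 2:
        raise ValueError("too few positive points for a log-linear fit")
    slope = np.polyfit(trace.time[keep], np.log(y[keep]), 1)[0]
    return float(-slope)


def flow_summary(
    events: pd.DataFrame,
    channels: Sequence[str],
    control_group: str,
    tmrm_channel: Optional[str] = None,
    mtg_channel: Optional[str] = None,
) -> FlowSummary:
    """Reduce a per-event intensity table to per-sample MFIs and fold changes.

    ``events`` needs ``sample_id`` and ``group`` columns plus one column per
    channel. MFI is the arithmetic mean over events; when the potential
    (TMRM) and mass (MitoTracker Green) channels are named, their MFI ratio
    is added. Fold changes divide each sample's MFI by the control-group
    mean MFI, so the control group averages to 1.
    """
    required = {"sample_id", "group", *channels}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table is missing columns: {sorted(missing)}")
    grouped = events.groupby("sample_id", sort=True)
    empty = [s for s, df in grouped if len(df) == 0]
    if empty:
        raise ValueError(f"samples with zero events: {empty}")
    mfi = grouped[list(channels)].mean()
    mfi["group"] = grouped["group"].first()

    if tmrm_channel and mtg_channel:
        ratio = mfi[tmrm_channel] / mfi[mtg_channel]
        ratio.name = "tmrm_mtg_ratio"
    else:
        ratio = pd.Series(dtype=float, name="tmrm_mtg_ratio")

    control = mfi[mfi["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    control_means = control[list(channels)].mean()
    fold = mfi[list(channels)] / control_means
    fold["group"] = mfi["group"]
    return FlowSummary(mfi=mfi, ratio=ratio, fold_change=fold, control_group=control_group)
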
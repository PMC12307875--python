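"""Transcriptomic screening: volcano filtering, mitochondrial-gene mapping
and 2^-ΔΔCt qRT-PCR quantification.

The screening stage starts from an upstream per-gene statistics table (gene
symbol, log2 fold change, p-value) — count modeling and normalization are
out of scope. Genes are called up/down at the standard |log2FC| >= 2,
p <= 0.01 cutoffs (both boundaries inclusive), then intersected with a
user-supplied mitochondrial gene list (e.g. a MitoCarta-style inventory),
matched case-insensitively.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_LFC_CUT = 2.0
DEFAULT_P_CUT = 0.01

REQUIRED_COLUMNS = ("gene", "log2fc", "pvalue")


def volcano_filter(
    table: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> pd.DataFrame:
    """Call each gene up / down / unchanged at the volcano-plot cutoffs.

    up: log2fc >= lfc_cut and p <= p_cut; down: log2fc <= -lfc_cut and
    p <= p_cut; everything else unchanged. Both boundaries are inclusive.
    Returns a copy of the table with a ``direction`` column; the three calls
    partition the table.
    """
    if lfc_cut <= 0 or p_cut <= 0:
        raise ValueError("cutoffs must be > 0")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table is missing required columns: {missing}")
    calls = table.copy()
    lfc = calls["log2fc"].to_numpy(dtype=float)
    p = calls["pvalue"].to_numpy(dtype=float)
    if not np.all(np.isfinite(lfc)):
        raise ValueError("log2fc contains non-finite values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    direction = np.full(len(calls), "unchanged", dtype=object)
    significant = p <= p_cut
    direction[significant & (lfc >= lfc_cut)] = "up"
    direction[significant & (lfc <= -lfc_cut)] = "down"
    calls["direction"] = direction
    return calls


def map_mitochondrial(
    calls: pd.DataFrame,
    mito_genes: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag calls whose symbol is in the mitochondrial gene list.

    Matching is case-insensitive on stripped symbols. Returns the annotated
    calls (new ``is_mitochondrial`` column) and a direction × membership
    summary count table.
    """
    mito = {str(g).strip().upper() for g in mito_genes}
    if not mito:
        raise ValueError("mitochondrial gene list is empty")
    annotated = calls.copy()
    annotated["is_mitochondrial"] = (
        annotated["gene"].astype(str).str.strip().str.upper().isin(mito)
    )
    summary = (
        annotated.groupby(["direction", "is_mitochondrial"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(["up", "down", "unchanged"], fill_value=0)
    )
    summary.columns = ["other" if not c else "mitochondrial" for c in summary.columns]
    return annotated, summary


def ddct(
    ct_target_treated: Sequence[float],
    ct_reference_treated: Sequence[float],
    ct_target_control: Sequence[float],
    ct_reference_control: Sequence[float],
) -> float:
    """Relative expression by the 2^-ΔΔCt method.

    ΔCt = mean Ct(target) - mean Ct(reference) within each condition;
    ΔΔCt = ΔCt(treated) - ΔCt(control); returned value is 2^(-ΔΔCt).
    Invariant to any constant offset applied to both genes of one condition.
    """
    cells = {
        "target/treated": ct_target_treated,
        "reference/treated": ct_reference_treated,
        "target/control": ct_target_control,
        "reference/control": ct_reference_control,
    }
    means = {}
    for name, values in cells.items():
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        if arr.size == 0:
            raise ValueError(f"no Ct replicates for {name}")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"Ct values for {name} must be finite and > 0")
        means[name] = arr.mean()
    dct_treated = means["target/treated"] - means["reference/treated"]
    dct_control = means["target/control"] - means["reference/control"]
    return float(2.0 ** -(dct_treated - dct_control))


def ddct_from_frame(ct_table: pd.DataFrame) -> float:
    """2^-ΔΔCt from a tidy Ct table.

    Expects columns ``gene_role`` in {target, reference}, ``condition`` in
    {treated, control}, and ``ct``; replicates are rows.
    """
    needed = {"gene_role", "condition", "ct"}
    missing = needed - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")

    def cell(role: str, cond: str) -> np.ndarray:
        sel = ct_table[(ct_table["gene_role"] == role) & (ct_table["condition"] == cond)]
        if sel.empty:
            raise ValueError(f"missing Ct values for {role}/{cond}")
        return sel["ct"].to_numpy(dtype=float)

    return ddct(
        cell("target", "treated"),
        cell("reference", "treated"),
        cell("target", "control"),
        cell("reference", "control"),
    )
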
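"""Per-sample contamination statistics.

Contamination index (CI): summed linear MS intensity of the cell-type marker
proteins detected in a sample divided by the summed intensity of all other
detected proteins in that same sample.  Being a within-sample ratio of sums,
the CI is invariant to any global rescaling of a sample and increases
monotonically with the amount of contaminant material captured.

Cellular enrichment score (ES): summed intensity of the top-30 cell-specific
markers divided by the summed intensity of the top-30 most abundant plasma
proteins in the same sample — how strongly cellular material competes with
the dominant plasma proteome.

All sums are computed on linear intensities; undefined conditions (empty
denominator) surface as explicit flags, never as NaN/Inf leaking into
reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markers import MarkerPanel
from .quant import QuantMatrix

__all__ = [
    "contamination_index",
    "top_plasma_proteins",
    "enrichment_score",
    "contaminant_enrichment_factor",
    "zscore_panel",
]


def _panel_ids(panel) -> list[str]:
    if isinstance(panel, MarkerPanel):
        return panel.protein_ids
    return list(panel)


def contamination_index(matrix: QuantMatrix, panel) -> pd.DataFrame:
    """Contamination index per sample.

    Returns a DataFrame indexed by sample with columns ``ci``,
    ``marker_sum``, ``other_sum``, ``n_markers_detected``, ``undefined`` and
    ``n_markers_absent`` (markers not in the matrix universe at all).
    Missing values contribute zero to both sums; a sample whose detected
    proteins are all markers has an undefined CI (flag, not infinity).
    """
    matrix.require_linear("contamination_index")
    ids = _panel_ids(panel)
    if not ids:
        raise ValueError("marker panel is empty")
    universe = matrix.protein_ids
    present_ids = [p for p in ids if p in universe]
    n_absent = len(ids) - len(present_ids)
    is_marker = universe.isin(present_ids)
    values = matrix.intensities.to_numpy(dtype=float)
    filled = np.nan_to_num(values, nan=0.0)
    marker_sum = filled[is_marker].sum(axis=0)
    other_sum = filled[~is_marker].sum(axis=0)
    n_detected = matrix.detected().to_numpy()[is_marker].sum(axis=0)
    undefined = other_sum == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(undefined, np.nan, marker_sum / np.where(undefined, 1.0, other_sum))
    return pd.DataFrame(
        {
            "ci": ci,
            "marker_sum": marker_sum,
            "other_sum": other_sum,
            "n_markers_detected": n_detected.astype(int),
            "undefined": undefined,
            "n_markers_absent": n_absent,
        },
        index=matrix.sample_ids,
    )


def top_plasma_proteins(
    reference: QuantMatrix, n: int = 30, exclude=()
) -> list[str]:
    """Top-``n`` proteins of a reference plasma sample set by mean intensity.

    ``exclude`` removes marker proteins before ranking so the denominator of
    the enrichment score is genuinely plasma-derived.
    """
    reference.require_linear("top_plasma_proteins")
    mean = reference.intensities.mean(axis=1)
    mean = mean.drop(index=[p for p in exclude if p in mean.index])
    mean = mean.dropna().sort_values(ascending=False, kind="mergesort")
    return mean.head(n).index.tolist()


def enrichment_score(matrix: QuantMatrix, panel, plasma_top30) -> pd.DataFrame:
    """Cellular enrichment score per sample.

    ES = sum of the (top-30) marker intensities / sum of the top-30 plasma
    protein intensities, both within the same sample.  If none of the plasma
    top-30 is detected in a sample the score is flagged undefined.
    """
    matrix.require_linear("enrichment_score")
    ids = _panel_ids(panel)[:30]
    plasma_ids = list(plasma_top30)
    universe = matrix.protein_ids
    filled = matrix.intensities.fillna(0.0)
    marker_sum = filled.reindex([p for p in ids if p in universe]).sum(axis=0)
    plasma_present = [p for p in plasma_ids if p in universe]
    plasma_sum = filled.reindex(plasma_present).sum(axis=0)
    undefined = plasma_sum == 0.0
    es = marker_sum.where(~undefined) / plasma_sum.where(~undefined)
    return pd.DataFrame(
        {"es": es, "marker_sum": marker_sum, "plasma_top_sum": plasma_sum,
         "undefined": undefined}
    )


def contaminant_enrichment_factor(
    matrix: QuantMatrix,
    panel,
    sample_ids,
    reference_ids,
    method: str = "ci",
    plasma_top30=None,
) -> pd.DataFrame:
    """Ratio of a sample's contamination statistic to a matched reference.

    The reference should be a pure-plasma measurement under the same
    workflow.  ``method="ci"`` (default) ratios contamination indices;
    ``method="es"`` ratios enrichment scores (requires ``plasma_top30``).
    A zero or undefined reference makes the factor undefined (flagged).
    """
    if method == "ci":
        scores = contamination_index(matrix, panel)["ci"]
    elif method == "es":
        if plasma_top30 is None:
            raise ValueError("method='es' requires plasma_top30")
        scores = enrichment_score(matrix, panel, plasma_top30)["es"]
    else:
        raise ValueError(f"unknown method {method!r}")
    ref = scores.reindex(list(reference_ids)).mean()
    sample_scores = scores.reindex(list(sample_ids))
    undefined = not np.isfinite(ref) or ref == 0.0
    factor = sample_scores / ref if not undefined else pd.Series(
        np.nan, index=sample_scores.index
    )
    return pd.DataFrame(
        {"factor": factor, "score": sample_scores, "reference_score": ref,
         "undefined": undefined | sample_scores.isna()}
    )


def zscore_panel(
    matrix: QuantMatrix, panel, top_n: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Z-score marker intensities across samples (log10 input required).

    Per protein, z = (x - mean) / sd across all samples, population sd on
    detected values only; a protein with zero sd gets z = 0 wherever
    detected, and a protein detected in fewer than two samples is excluded
    from the per-sample summary (its z stays undefined).  Returns the
    proteins x samples Z matrix for the top ``top_n`` panel proteins and the
    per-sample mean Z over detected panel proteins.
    """
    matrix.require_log10("zscore_panel")
    ids = _panel_ids(panel)
    if top_n is not None:
        if top_n > len(ids):
            raise ValueError("top_n exceeds panel length")
        ids = ids[:top_n]
    ids = [p for p in ids if p in matrix.protein_ids]
    sub = matrix.intensities.reindex(ids)
    values = sub.to_numpy(dtype=float)
    detected = ~np.isnan(values)
    n_det = detected.sum(axis=1)
    mean = np.nanmean(np.where(detected, values, np.nan), axis=1)
    sd = np.zeros_like(mean)
    enough = n_det >= 2
    with np.errstate(invalid="ignore"):
        sd[enough] = np.nanstd(np.where(detected, values, np.nan), axis=1, ddof=0)[enough]
    z = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        if not enough[i]:
            continue
        row = values[i]
        if sd[i] == 0.0:
            z[i][detected[i]] = 0.0
        else:
            z[i][detected[i]] = (row[detected[i]] - mean[i]) / sd[i]
    z_frame = pd.DataFrame(z, index=sub.index, columns=sub.columns)
    per_sample = z_frame.mean(axis=0, skipna=True)
    return z_frame, per_sample
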
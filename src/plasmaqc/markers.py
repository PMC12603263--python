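"""Derivation of cell-type contamination marker panels.

Markers are mined from a pure-contaminant vs pure-plasma replicate
comparison with a conjunction of four filters: fold enrichment over plasma,
a minimum precursor count, a minimum mean log10 intensity in the contaminant,
and a replicate-CV ceiling.  Defaults follow the published criteria:
>1000-fold enrichment for platelets/erythrocytes (>100 for PBMCs), at least
two precursors, log10 intensity above 7.5 / 8.2 / 7.1, CV below 20% / 20% /
35%.  Proteins never detected in plasma are cell-exclusive; they are aligned
to the top of the fold-change axis at a slightly higher fold change than the
largest finite one (multiplier 1.1, configurable), so that exclusive
proteins outrank every shared one.

The abundance threshold is applied to the contaminant-side mean intensity
(the only side where candidate markers are reliably detected).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quant import QuantMatrix, read_marker_panel_frame, write_marker_panel_frame

__all__ = [
    "FilterCriteria",
    "MarkerPanel",
    "DEFAULT_CRITERIA",
    "REFERENCE_TOP5_PANELS",
    "compute_fold_changes",
    "select_markers",
    "compare_panels",
]

#: published top-5 marker gene symbols per contaminant cell type, shipped for
#: exact string matching against gene-symbol-keyed user data
REFERENCE_TOP5_PANELS = {
    "platelet": ["ACTB", "PFN1", "THBS1", "TPM4", "TLN1"],
    "erythrocyte": ["HBB", "HBA1", "HBD", "HBG2", "CA1"],
    "pbmc": ["H4C1", "H2AZ1", "H2BC3", "H2BC14", "RAP1B"],
}


@dataclasses.dataclass(frozen=True)
class FilterCriteria:
    """Marker selection thresholds (all four filters are a conjunction)."""

    min_fold_change: float = 1000.0
    min_precursors: int = 2
    min_log10_intensity: float = 7.5
    max_cv: float = 0.20
    panel_size: int = 30
    exclusive_fc_multiplier: float = 1.1

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if min(self.min_fold_change, self.exclusive_fc_multiplier) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def for_cell_type(cls, cell_type: str) -> "FilterCriteria":
        return DEFAULT_CRITERIA[cell_type]


DEFAULT_CRITERIA = {
    "platelet": FilterCriteria(1000.0, 2, 7.5, 0.20),
    "erythrocyte": FilterCriteria(1000.0, 2, 8.2, 0.20),
    "pbmc": FilterCriteria(100.0, 2, 7.1, 0.35),
}


@dataclasses.dataclass
class MarkerPanel:
    """Ordered contamination marker panel for one cell type.

    ``entries`` is a DataFrame with columns protein_id, fold_change,
    mean_log10_intensity, cv, exclusive, rank — sorted by fold change
    descending (ties by protein_id ascending).
    """

    cell_type: str
    entries: pd.DataFrame
    criteria: FilterCriteria | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.entries["protein_id"].duplicated().any():
            raise ValueError("marker panel contains duplicate proteins")

    @property
    def protein_ids(self) -> list[str]:
        return self.entries["protein_id"].tolist()

    def top(self, depth: int) -> list[str]:
        return self.entries["protein_id"].head(depth).tolist()

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        frame = self.entries.copy()
        frame.insert(1, "cell_type", self.cell_type)
        return frame

    def save(self, path) -> None:
        write_marker_panel_frame(self.to_frame(), path)

    @classmethod
    def load(cls, path) -> "MarkerPanel":
        frame = read_marker_panel_frame(path)
        cell_types = frame["cell_type"].unique()
        if len(cell_types) != 1:
            raise ValueError("panel file must contain exactly one cell type")
        entries = frame.drop(columns=["cell_type"]).reset_index(drop=True)
        return cls(cell_type=str(cell_types[0]), entries=entries, source=str(path))

    @classmethod
    def from_protein_ids(cls, cell_type: str, protein_ids, source="designed") -> "MarkerPanel":
        """Panel from a plain id list (e.g. simulator ground truth)."""
        ids = list(protein_ids)
        entries = pd.DataFrame(
            {
                "protein_id": ids,
                "fold_change": np.nan,
                "mean_log10_intensity": np.nan,
                "cv": np.nan,
                "exclusive": True,
                "rank": np.arange(1, len(ids) + 1),
            }
        )
        return cls(cell_type=cell_type, entries=entries, source=source)


def compute_fold_changes(
    pure_contaminant: QuantMatrix,
    pure_plasma: QuantMatrix,
    exclusive_fc_multiplier: float = 1.1,
) -> pd.DataFrame:
    """Per-protein enrichment of a pure contaminant over pure plasma.

    Means are taken over detected replicates on the linear scale; the CV
    (population sd / mean) comes from the contaminant replicates.  Proteins
    never detected in the contaminant are dropped; proteins detected in the
    contaminant but never in plasma are flagged ``exclusive`` and assigned
    ``exclusive_fc_multiplier`` x the largest finite fold change observed.
    """
    pure_contaminant.require_linear("compute_fold_changes")
    pure_plasma.require_linear("compute_fold_changes")
    if len(pure_contaminant.protein_ids.intersection(pure_plasma.protein_ids)) == 0:
        raise ValueError(
            "contaminant and plasma matrices share no proteins; "
            "fold changes are undefined"
        )
    cont = pure_contaminant.intensities
    if cont.shape[1] < 2:
        warnings.warn("single contaminant replicate: CV undefined, CV filter disabled")
        cv = pd.Series(np.nan, index=cont.index)
    else:
        mean = cont.mean(axis=1)
        sd = cont.std(axis=1, ddof=0)
        cv = sd / mean
    mean_cont = cont.mean(axis=1)
    detected = mean_cont.notna()
    mean_cont = mean_cont[detected]
    cv = cv[detected]
    mean_plasma = pure_plasma.intensities.mean(axis=1).reindex(mean_cont.index)

    fold = mean_cont / mean_plasma
    exclusive = mean_plasma.isna()
    finite = fold[np.isfinite(fold)]
    if exclusive.any():
        if finite.empty:
            raise ValueError("all contaminant proteins are plasma-exclusive; "
                             "no finite fold change to align to")
        fold = fold.where(~exclusive, exclusive_fc_multiplier * finite.max())

    if pure_contaminant.precursor_counts is not None:
        precursors = pure_contaminant.precursor_counts.reindex(mean_cont.index)
    else:
        precursors = pd.Series(np.nan, index=mean_cont.index)

    table = pd.DataFrame(
        {
            "mean_contaminant": mean_cont,
            "mean_plasma": mean_plasma,
            "fold_change": fold,
            "mean_log10_intensity": np.log10(mean_cont),
            "cv": cv,
            "max_precursors": precursors,
            "exclusive": exclusive,
        }
    )
    table.index.name = "protein_id"
    return table


def select_markers(
    fc_table: pd.DataFrame,
    criteria: FilterCriteria | None = None,
    cell_type: str = "platelet",
    source: str = "",
) -> MarkerPanel:
    """Apply the four-filter cascade and rank survivors by fold change.

    The cascade is a pure conjunction (order-free); survivors are sorted by
    fold change descending with deterministic protein-id tie-break and
    truncated to the panel size.  A short panel is emitted with a warning,
    never padded.
    """
    if criteria is None:
        criteria = FilterCriteria.for_cell_type(cell_type)
    keep = fc_table["fold_change"] > criteria.min_fold_change
    keep &= fc_table["mean_log10_intensity"] > criteria.min_log10_intensity
    if fc_table["max_precursors"].notna().any():
        keep &= fc_table["max_precursors"] >= criteria.min_precursors
    if fc_table["cv"].notna().any():
        keep &= fc_table["cv"] < criteria.max_cv
    else:
        warnings.warn("CV unavailable; CV filter disabled")
    survivors = fc_table[keep].reset_index()
    if "protein_id" not in survivors.columns:
        survivors = survivors.rename(columns={survivors.columns[0]: "protein_id"})
    survivors = survivors.sort_values(
        ["fold_change", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if len(survivors) < criteria.panel_size:
        warnings.warn(
            f"only {len(survivors)} proteins pass the marker criteria "
            f"(panel_size={criteria.panel_size}); emitting a short panel"
        )
    survivors = survivors.head(criteria.panel_size)
    entries = survivors[
        ["protein_id", "fold_change", "mean_log10_intensity", "cv", "exclusive"]
    ].copy()
    entries["rank"] = np.arange(1, len(entries) + 1)
    return MarkerPanel(cell_type=cell_type, entries=entries,
                       criteria=criteria, source=source)


def compare_panels(a: MarkerPanel, b: MarkerPanel, depth: int = 30) -> dict:
    """Overlap of two panels' top-``depth`` entries (symmetric).

    Returns overlap count, Jaccard index of the two top sets, and the
    Spearman rank correlation of the shared proteins' ranks.
    """
    if a.cell_type != b.cell_type:
        raise ValueError("panels compare only within one cell type")
    note = ""
    effective = min(depth, len(a), len(b))
    if effective < depth:
        note = f"compared at depth {effective} (panel shorter than {depth})"
    top_a = a.top(effective)
    top_b = b.top(effective)
    shared = sorted(set(top_a) & set(top_b))
    union = set(top_a) | set(top_b)
    if len(shared) >= 2:
        rank_a = [top_a.index(p) for p in shared]
        rank_b = [top_b.index(p) for p in shared]
        rho = float(stats.spearmanr(rank_a, rank_b).statistic)
    else:
        rho = np.nan
    return {
        "depth": effective,
        "overlap": len(shared),
        "jaccard": len(shared) / len(union) if union else np.nan,
        "rank_correlation": rho,
        "note": note,
    }
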
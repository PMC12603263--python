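"""Characterisation of how a workflow reshapes the plasma proteome.

Taking the neat workflow as the baseline, proteins are ranked by their neat
abundance and each protein's intensity change in an alternative workflow is
tracked (rank-abundance shift profile).  Proteins whose intensity differs
strongly from neat are classed enriched/depleted, and the physicochemical
properties of the two classes are compared per feature with Welch t-tests —
the signature of bead workflows is significant enrichment of smaller,
shorter proteins.  The module also provides replicate-CV distributions and
PCA with K-nearest-neighbour imputation for incomplete log-scale matrices.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .quant import QuantMatrix
from .seqprops import ProteinProperties, sequence_properties

__all__ = [
    "rank_shift_profile",
    "classify_enriched_depleted",
    "properties_from_fasta",
    "property_enrichment_tests",
    "replicate_cv",
    "pca_with_imputation",
    "PCAResult",
]

PROPERTY_NAMES = [
    "molecular_weight",
    "length",
    "isoelectric_point",
    "gravy",
    "aromaticity",
    "instability_index",
]


def rank_shift_profile(neat: pd.Series, other: pd.Series) -> pd.DataFrame:
    """Per-protein abundance shift of a workflow relative to neat.

    ``neat`` and ``other`` are mean linear-intensity sample vectors.  Ranks
    are assigned by neat intensity descending (ties by protein id);
    ``log10_ratio`` is defined where both workflows detect the protein, and
    proteins seen by only one side are classed ``neat_only``/``other_only``.
    """
    neat = pd.Series(neat, dtype=float)
    other = pd.Series(other, dtype=float)
    neat_det = neat.dropna()
    if neat_det.empty:
        raise ValueError("neat sample is empty")
    if len(neat_det.index.intersection(other.dropna().index)) == 0:
        warnings.warn("neat and workflow universes are disjoint; only-classes emitted")
    order = neat_det.sort_values(ascending=False, kind="mergesort")
    order = order.loc[
        sorted(order.index, key=lambda p: (-order[p], p))
    ]
    universe = neat.index.union(other.index, sort=False)
    profile = pd.DataFrame(index=universe)
    profile["neat_intensity"] = neat.reindex(universe)
    profile["other_intensity"] = other.reindex(universe)
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    profile["neat_rank"] = ranks.reindex(universe)
    both = profile["neat_intensity"].notna() & profile["other_intensity"].notna()
    with np.errstate(divide="ignore"):
        profile["log10_ratio"] = np.where(
            both,
            np.log10(profile["other_intensity"] / profile["neat_intensity"]),
            np.nan,
        )
    profile["class"] = np.select(
        [
            both,
            profile["neat_intensity"].notna(),
            profile["other_intensity"].notna(),
        ],
        ["neither", "neat_only", "other_only"],
        default="absent",
    )
    profile.index.name = "protein_id"
    return profile


def classify_enriched_depleted(
    profile: pd.DataFrame,
    threshold_fraction: float = 0.8,
    mode: str = "linear",
) -> pd.Series:
    """Class labels from the shift profile.

    ``mode="linear"`` reads "differs by >= 80%" literally: enriched when
    other/neat >= 1 + threshold (1.8), depleted when other/neat <= 1 -
    threshold (0.2).  ``mode="log2"`` instead uses a symmetric |log2 FC|
    cutoff of log2(1 + threshold).  Only-one-side classes pass through.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    ratio = 10.0 ** profile["log10_ratio"]
    tol = 1e-9  # boundary values (exactly 1 +/- threshold) count
    if mode == "linear":
        enriched = ratio >= 1.0 + threshold_fraction - tol
        depleted = ratio <= 1.0 - threshold_fraction + tol
    elif mode == "log2":
        cut = np.log2(1.0 + threshold_fraction)
        enriched = np.log2(ratio) >= cut - tol
        depleted = np.log2(ratio) <= -cut + tol
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = pd.Series(profile["class"], index=profile.index, dtype=object)
    both = profile["log10_ratio"].notna()
    labels[both & enriched] = "enriched"
    labels[both & depleted] = "depleted"
    labels[both & ~enriched & ~depleted] = "neither"
    return labels


def properties_from_fasta(path) -> pd.DataFrame:
    """Compute the six sequence properties for every record in a FASTA file.

    Record ids are the description line up to the first whitespace.
    """
    from Bio import SeqIO

    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        props = sequence_properties(str(record.seq), protein_id=record.id)
        rows.append(dataclasses.asdict(props))
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.set_index("protein_id")
    return frame


def property_enrichment_tests(
    enriched: pd.DataFrame, depleted: pd.DataFrame
) -> pd.DataFrame:
    """Welch two-sided t-test per physicochemical property.

    ``enriched``/``depleted`` are property tables (rows = proteins, columns
    include the six features).  Fewer than three proteins per side makes the
    property undefined; zero variance on both sides with equal means gives
    p = 1 by convention (flagged).  Direction reports which side has the
    larger mean.
    """
    rows = []
    for prop in PROPERTY_NAMES:
        a = enriched[prop].dropna().to_numpy(dtype=float) if prop in enriched else np.array([])
        b = depleted[prop].dropna().to_numpy(dtype=float) if prop in depleted else np.array([])
        if len(a) < 3 or len(b) < 3:
            rows.append({"property": prop, "t": np.nan, "p_value": np.nan,
                         "neg_log10_p": np.nan, "direction": None,
                         "note": "fewer than 3 proteins on a side"})
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                rows.append({"property": prop, "t": 0.0, "p_value": 1.0,
                             "neg_log10_p": 0.0, "direction": "none",
                             "note": "zero variance both sides"})
                continue
        res = stats.ttest_ind(a, b, equal_var=False)
        p = float(res.pvalue)
        direction = "enriched higher" if a.mean() > b.mean() else "depleted higher"
        rows.append({"property": prop, "t": float(res.statistic), "p_value": p,
                     "neg_log10_p": float(-np.log10(max(p, 1e-300))),
                     "direction": direction, "note": ""})
    return pd.DataFrame(rows)


def replicate_cv(matrix: QuantMatrix, replicate_groups: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein CV per replicate group plus distribution summaries.

    ``replicate_groups`` maps a group label to its sample-id list (each of
    size >= 2).  CV = population sd / mean on linear intensities over the
    detected replicates; proteins detected fewer than twice in a group are
    excluded there.  Returns (per-protein CV table, summary with median and
    quartiles per group).
    """
    matrix.require_linear("replicate_cv")
    cv_table = {}
    for label, sample_ids in replicate_groups.items():
        if len(sample_ids) < 2:
            raise ValueError(f"replicate group {label!r} has fewer than 2 samples")
        sub = matrix.intensities.loc[:, list(sample_ids)]
        n_det = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
        cv = (sd / mean).where(n_det >= 2)
        cv_table[label] = cv
    cv_frame = pd.DataFrame(cv_table)
    if cv_frame.notna().sum().sum() == 0:
        raise ValueError("no group has proteins detected in >= 2 replicates")
    summary = pd.DataFrame(
        {
            "median_cv": cv_frame.median(),
            "q1_cv": cv_frame.quantile(0.25),
            "q3_cv": cv_frame.quantile(0.75),
            "n_proteins": cv_frame.notna().sum(),
        }
    )
    summary.index.name = "group"
    return cv_frame, summary


@dataclasses.dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # proteins x components
    variance_fractions: np.ndarray
    imputed: pd.DataFrame           # samples x proteins after KNN imputation


def pca_with_imputation(
    matrix: QuantMatrix, k_neighbors: int = 3, n_components: int | None = None
) -> PCAResult:
    """Column-centred PCA of a log10 matrix after KNN imputation.

    Imputation works in sample space: a sample's missing protein is filled
    with the mean of its ``k_neighbors`` nearest samples by Euclidean
    distance over shared detected proteins.  Proteins detected fewer than
    twice are dropped beforehand.  PCA is plain SVD of the column-centred
    samples x proteins matrix; a complete matrix makes imputation the
    identity.
    """
    matrix.require_log10("pca_with_imputation")
    n_samples = matrix.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if k_neighbors >= n_samples:
        raise ValueError("k_neighbors must be smaller than the number of samples")
    keep = matrix.detected().sum(axis=1) >= 2
    data = matrix.intensities.loc[keep].T  # samples x proteins
    if data.isna().to_numpy().any():
        imputer = KNNImputer(n_neighbors=k_neighbors)
        imputed = pd.DataFrame(
            imputer.fit_transform(data), index=data.index, columns=data.columns
        )
    else:
        imputed = data.copy()
    centred = imputed - imputed.mean(axis=0)
    u, s, vt = np.linalg.svd(centred.to_numpy(dtype=float), full_matrices=False)
    var = s**2
    fractions = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    if n_components is None:
        n_components = min(len(s), n_samples - 1)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components], index=imputed.index, columns=comps
    )
    loadings = pd.DataFrame(
        vt[:n_components].T, index=imputed.columns, columns=comps
    )
    return PCAResult(scores, loadings, fractions[:n_components], imputed)
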
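"""Three-step contamination control for biomarker studies.

1. *Per-sample assessment*: compute contamination indices against validated
   marker panels and flag outliers relative to the study-specific baseline
   (median + k * MAD on log10(CI + eps); one-sided — only unusually high
   contamination is flagged).
2. *Group-bias detection*: nonparametric location tests (Mann-Whitney U for
   two groups, Kruskal-Wallis beyond) of the contamination index between
   study groups; contamination distributions are heavy-tailed by
   construction, so rank tests are the safe default.
3. *Candidate validation*: Spearman correlation of each candidate biomarker
   against every panel protein (and against the per-sample CI) across
   samples; a candidate whose profile tracks contamination markers is
   flagged as a likely artifact.  The correlation flag is a screening rule
   on |rho|, not an inference, and is deliberately uncorrected.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import contamination_index
from .quant import QuantMatrix

__all__ = [
    "QCReport",
    "assess_samples",
    "detect_group_bias",
    "candidate_correlation_map",
    "run_qc",
]


@dataclasses.dataclass
class QCReport:
    """Machine-readable outcome of the three-step strategy."""

    per_sample: pd.DataFrame
    group_bias: pd.DataFrame
    candidate_validation: pd.DataFrame
    parameters: dict


#: consistency constant making the MAD estimate the normal-equivalent sigma
MAD_SCALE = 1.4826


def assess_samples(
    ci: pd.Series,
    k_mad: float = 3.0,
    eps: float = 1e-6,
    min_samples: int = 5,
    scale_mad: bool = True,
) -> pd.DataFrame:
    """Flag high-contamination outliers against the study baseline.

    The baseline is the study median of log10(CI + eps); a sample is flagged
    when its value exceeds median + ``k_mad`` * MAD (median absolute
    deviation; by default the standard consistency-scaled MAD, so ``k_mad=3``
    is the usual three-sigma-equivalent robust rule — set
    ``scale_mad=False`` for the raw MAD).  One-sided: only unusually high
    contamination flags.  With fewer than ``min_samples`` defined indices
    the baseline is meaningless and every flag is ``undefined``.  Flags are
    tri-state: pass / flag / undefined.
    """
    ci = pd.Series(ci, dtype=float)
    defined = ci.notna()
    if defined.sum() == 0:
        raise ValueError("all contamination indices are undefined")
    log_ci = np.log10(ci[defined] + eps)
    flags = pd.Series("undefined", index=ci.index, dtype=object)
    if defined.sum() < min_samples:
        warnings.warn(
            f"fewer than {min_samples} samples with a defined index; "
            "outlier flags undefined"
        )
        baseline = mad = np.nan
    else:
        baseline = float(np.median(log_ci))
        mad = float(np.median(np.abs(log_ci - baseline)))
        if scale_mad:
            mad *= MAD_SCALE
        threshold = baseline + k_mad * mad
        flags[defined] = np.where(log_ci > threshold, "flag", "pass")
    return pd.DataFrame(
        {
            "ci": ci,
            "log10_ci": np.where(defined, np.log10(ci + eps), np.nan),
            "outlier_flag": flags,
            "baseline_median": baseline,
            "baseline_mad": mad,
        }
    )


def detect_group_bias(
    ci: pd.Series,
    groups: pd.Series,
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> dict:
    """Test whether contamination differs between study groups.

    Two groups: two-sided Mann-Whitney U; more: Kruskal-Wallis, with
    pairwise Mann-Whitney follow-up when the omnibus test flags.  Returns
    test name, statistic, p-value, group medians, effect direction and the
    bias flag (p < alpha).  Groups below ``min_group_size`` make the result
    undefined.
    """
    ci = pd.Series(ci, dtype=float)
    groups = pd.Series(groups).reindex(ci.index)
    ok = ci.notna() & groups.notna()
    ci, groups = ci[ok], groups[ok]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {g: ci[groups == g].to_numpy() for g in labels}
    sizes = {g: len(v) for g, v in samples.items()}
    medians = {g: float(np.median(v)) if len(v) else np.nan for g, v in samples.items()}
    if min(sizes.values()) < min_group_size:
        return {
            "test": None, "statistic": np.nan, "p_value": np.nan,
            "group_medians": medians, "group_sizes": sizes,
            "direction": None, "bias_flag": "undefined",
            "note": f"a group is below the minimum size {min_group_size}",
        }
    values = [samples[g] for g in labels]
    if len(labels) == 2:
        a, b = values
        if np.ptp(np.concatenate(values)) == 0:
            stat, p = float(len(a) * len(b) / 2), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "mann-whitney-u"
        direction = f"{labels[int(medians[labels[1]] > medians[labels[0]])]} higher"
        pairwise = None
    else:
        if np.ptp(np.concatenate(values)) == 0:
            stat, p = 0.0, 1.0
        else:
            res = stats.kruskal(*values)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "kruskal-wallis"
        direction = f"{max(medians, key=medians.get)} highest"
        pairwise = []
        if p < alpha:
            for g1, g2 in itertools.combinations(labels, 2):
                if np.ptp(np.concatenate([samples[g1], samples[g2]])) == 0:
                    pp = 1.0
                else:
                    pp = float(stats.mannwhitneyu(
                        samples[g1], samples[g2], alternative="two-sided"
                    ).pvalue)
                pairwise.append({"groups": (g1, g2), "p_value": pp})
    result = {
        "test": test, "statistic": stat, "p_value": p,
        "group_medians": medians, "group_sizes": sizes,
        "direction": direction,
        "bias_flag": "flag" if p < alpha else "pass",
        "note": "",
    }
    if len(labels) > 2:
        result["pairwise"] = pairwise
    return result


def _spearman_pairwise(x: np.ndarray, y: np.ndarray, min_pairs: int) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_pairs:
        return np.nan
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return np.nan
    return float(stats.spearmanr(x[ok], y[ok]).statistic)


def candidate_correlation_map(
    matrix: QuantMatrix,
    candidates,
    panels,
    ci_table: pd.DataFrame | None = None,
    r_threshold: float = 0.7,
    min_pairs: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate candidate biomarkers with cell-specific markers.

    ``matrix`` must be log10 scale; correlations are Spearman,
    pairwise-complete, undefined below ``min_pairs`` paired detections.
    ``panels`` is a list of marker panels (or a single one).  A candidate is
    flagged as a contamination artifact when its max |rho| against any panel
    protein — or against the per-sample CI of any panel — reaches
    ``r_threshold``.  Returns (summary per candidate, full candidate x
    marker correlation map).
    """
    matrix.require_log10("candidate_correlation_map")
    if not isinstance(panels, (list, tuple)):
        panels = [panels]
    missing = [c for c in candidates if c not in matrix.protein_ids]
    if missing:
        raise ValueError(f"candidates absent from matrix: {missing}")
    data = matrix.intensities
    rows = []
    map_rows = []
    for cand in candidates:
        x = data.loc[cand].to_numpy(dtype=float)
        best_rho, best_marker, best_panel = np.nan, None, None
        for panel in panels:
            ids = [p for p in panel.protein_ids if p in data.index and p != cand]
            for pid in ids:
                rho = _spearman_pairwise(x, data.loc[pid].to_numpy(dtype=float),
                                         min_pairs)
                map_rows.append(
                    {"candidate": cand, "cell_type": panel.cell_type,
                     "marker": pid, "rho": rho}
                )
                if np.isnan(rho):
                    continue
                if np.isnan(best_rho) or abs(rho) > abs(best_rho):
                    best_rho, best_marker, best_panel = rho, pid, panel.cell_type
        rho_ci = np.nan
        if ci_table is not None:
            ci = ci_table["ci"].reindex(data.columns).to_numpy(dtype=float)
            rho_ci = _spearman_pairwise(x, ci, min_pairs)
        defined = not (np.isnan(best_rho) and np.isnan(rho_ci))
        hits = [abs(r) >= r_threshold for r in (best_rho, rho_ci) if not np.isnan(r)]
        rows.append(
            {
                "candidate": cand,
                "max_abs_rho": np.nan if np.isnan(best_rho) else abs(best_rho),
                "top_marker": best_marker,
                "top_marker_cell_type": best_panel,
                "rho_vs_ci": rho_ci,
                "artifact_flag": ("flag" if any(hits) else "pass") if defined
                                 else "undefined",
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(map_rows)


def run_qc(
    matrix: QuantMatrix,
    log_matrix: QuantMatrix,
    panels,
    groups: pd.Series | None = None,
    candidates=(),
    k_mad: float = 3.0,
    alpha: float = 0.05,
    r_threshold: float = 0.7,
) -> QCReport:
    """Execute the full three-step strategy and assemble a QCReport.

    ``matrix`` carries linear intensities for the index sums; ``log_matrix``
    the log10 view for correlations.  ``panels`` is a list of
    :class:`~plasmaqc.markers.MarkerPanel`.
    """
    if not isinstance(panels, (list, tuple)):
        panels = [panels]
    per_sample = pd.DataFrame({"sample_id": matrix.sample_ids})
    bias_rows = []
    ci_tables = {}
    for panel in panels:
        ci_table = contamination_index(matrix, panel)
        ci_tables[panel.cell_type] = ci_table
        assessed = assess_samples(ci_table["ci"], k_mad=k_mad)
        per_sample[f"ci_{panel.cell_type}"] = assessed["ci"].to_numpy()
        per_sample[f"flag_{panel.cell_type}"] = assessed["outlier_flag"].to_numpy()
        if groups is not None:
            bias = detect_group_bias(ci_table["ci"], groups, alpha=alpha)
            bias_rows.append(
                {
                    "cell_type": panel.cell_type,
                    "test": bias["test"],
                    "statistic": bias["statistic"],
                    "p_value": bias["p_value"],
                    "direction": bias["direction"],
                    "bias_flag": bias["bias_flag"],
                }
            )
    if candidates:
        primary_ci = ci_tables[panels[0].cell_type]
        summary, _ = candidate_correlation_map(
            log_matrix, list(candidates), list(panels),
            ci_table=primary_ci, r_threshold=r_threshold,
        )
    else:
        summary = pd.DataFrame(
            columns=["candidate", "max_abs_rho", "top_marker",
                     "top_marker_cell_type", "rho_vs_ci", "artifact_flag"]
        )
    return QCReport(
        per_sample=per_sample,
        group_bias=pd.DataFrame(
            bias_rows, columns=["cell_type", "test", "statistic", "p_value",
                                "direction", "bias_flag"]
        ),
        candidate_validation=summary,
        parameters={"k_mad": k_mad, "alpha": alpha, "r_threshold": r_threshold},
    )
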
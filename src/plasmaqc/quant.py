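"""Protein-group quantification matrices and the plain-text dialects around them.

The universal in-memory currency of the package is :class:`QuantMatrix`: a
proteins x samples table of linear-scale MS intensities with an explicit
missing marker (NaN).  DIA software conflates "not detected" with zero; by
default both empty cells and zeros are parsed as missing, because summed-
intensity metrics must not be corrupted by placeholder zeros (an undetected
marker then simply contributes nothing to a sum, which is the same thing).

Scale safety is enforced in types rather than by convention: a matrix carries
its scale ("linear" or "log10") and every sum-based metric in the package
calls :meth:`QuantMatrix.require_linear`, so feeding log-transformed data to a
linear-intensity statistic fails loudly instead of silently producing garbage.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QuantMatrix",
    "ScaleError",
    "read_quant_matrix",
    "write_quant_matrix",
    "log10_transform",
    "read_sample_table",
    "write_sample_table",
    "read_marker_panel_frame",
    "write_marker_panel_frame",
    "write_qc_report",
]

QC_REPORT_SCHEMA = "plasmaqc-qcreport/1"

#: annotation (non-sample) columns of the DIA-NN pg_matrix dialect
_DIANN_ANNOTATION_COLUMNS = (
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
)

_WIDE_ID_COLUMN = "ProteinGroup"


class ScaleError(TypeError):
    """A metric was handed a matrix on the wrong intensity scale."""


@dataclasses.dataclass
class QuantMatrix:
    """Proteins x samples intensity table with explicit missingness.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein-group id with sample ids as columns.
        NaN marks a missing (undetected) value.
    scale
        ``"linear"`` (raw MS intensities, the storage convention) or
        ``"log10"`` (a transformed view produced by :func:`log10_transform`).
    precursor_counts
        Optional per-protein precursor (peptide) counts, aligned to the
        protein index.
    """

    intensities: pd.DataFrame
    scale: str = "linear"
    precursor_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValueError(f"duplicate protein ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.intensities.to_numpy(dtype=float)
        if self.scale == "linear" and np.nanmin(values, initial=0.0) < 0:
            raise ValueError("linear-scale intensities must be nonnegative")
        if self.precursor_counts is not None:
            self.precursor_counts = self.precursor_counts.reindex(idx)

    # -- basic introspection -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def is_log(self) -> bool:
        return self.scale == "log10"

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (non-missing) values."""
        return self.intensities.notna()

    def require_linear(self, what: str) -> None:
        if self.scale != "linear":
            raise ScaleError(
                f"{what} is a summed-intensity statistic and requires a "
                f"linear-scale matrix; got scale={self.scale!r}"
            )

    def require_log10(self, what: str) -> None:
        if self.scale != "log10":
            raise ScaleError(
                f"{what} requires a log10-scale matrix (use log10_transform); "
                f"got scale={self.scale!r}"
            )

    def subset_samples(self, sample_ids) -> "QuantMatrix":
        return QuantMatrix(
            self.intensities.loc[:, list(sample_ids)].copy(),
            scale=self.scale,
            precursor_counts=self.precursor_counts,
        )

    def equals(self, other: "QuantMatrix", rtol: float = 1e-12) -> bool:
        """Value equality to ``rtol`` with an exact missingness pattern."""
        if self.scale != other.scale:
            return False
        if not self.intensities.index.equals(other.intensities.index):
            return False
        if not self.intensities.columns.equals(other.intensities.columns):
            return False
        a = self.intensities.to_numpy(dtype=float)
        b = other.intensities.to_numpy(dtype=float)
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            return False
        mask = ~np.isnan(a)
        return bool(np.allclose(a[mask], b[mask], rtol=rtol, atol=0.0))


# -- reading ------------------------------------------------------------------


def _sniff_dialect(header: list[str]) -> str:
    if header and header[0] == "Protein.Group":
        return "diann-pg"
    if header and header[0] == _WIDE_ID_COLUMN:
        return "wide-tsv"
    raise ValueError(
        f"cannot determine dialect from header {header[:3]}...: expected first "
        f"column {_WIDE_ID_COLUMN!r} (wide-tsv) or 'Protein.Group' (diann-pg). "
        "If samples are in rows and proteins in columns, transpose the table; "
        "plasmaqc requires proteins in rows."
    )


def read_quant_matrix(
    path,
    dialect: str | None = None,
    zeros_are_missing: bool = True,
) -> QuantMatrix:
    """Read a wide protein-group matrix from TSV.

    ``dialect`` is ``"wide-tsv"`` (first column ``ProteinGroup``) or
    ``"diann-pg"`` (DIA-NN ``pg_matrix`` report: ``Protein.Group`` plus
    annotation columns, then one numeric column per run).  ``None`` sniffs
    from the header.  Empty cells are always missing; zeros are missing too
    unless ``zeros_are_missing=False``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    header = list(raw.columns)
    if dialect is None:
        dialect = _sniff_dialect(header)
    if dialect == "wide-tsv":
        id_col = _WIDE_ID_COLUMN
        drop = []
    elif dialect == "diann-pg":
        id_col = "Protein.Group"
        drop = [c for c in _DIANN_ANNOTATION_COLUMNS[1:] if c in header]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if id_col not in header:
        raise ValueError(
            f"missing identifier column {id_col!r} for dialect {dialect!r}; "
            "if the table is transposed (samples in rows), transpose it first"
        )
    ids = raw[id_col]
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValueError(f"duplicate protein ids in {path.name}: {dups}")
    data = raw.drop(columns=[id_col] + drop)
    numeric = pd.DataFrame(index=data.index)
    for col in data.columns:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & data[col].notna() & (data[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric cell in {path.name} at row {row + 2}, column "
                f"{col!r}: {data[col][bad].iloc[0]!r}"
            )
        numeric[col] = converted
    numeric.index = pd.Index(ids, name="protein_id")
    if zeros_are_missing:
        numeric = numeric.mask(numeric == 0.0)
    return QuantMatrix(numeric)


def write_quant_matrix(matrix: QuantMatrix, path) -> None:
    """Write a matrix as wide TSV (missing values as empty cells)."""
    if matrix.is_log:
        raise ScaleError("matrices are stored on the linear scale only")
    out = matrix.intensities.copy()
    out.insert(0, _WIDE_ID_COLUMN, out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def log10_transform(matrix: QuantMatrix) -> QuantMatrix:
    """Return a log10-scale view; missing stays missing.

    Present values must be strictly positive: zeros should already have been
    treated as missing at read time.
    """
    matrix.require_linear("log10_transform input check")  # must start linear
    values = matrix.intensities.to_numpy(dtype=float)
    present = ~np.isnan(values)
    if np.any(values[present] <= 0):
        raise ValueError(
            "log10_transform: matrix contains nonpositive present values; "
            "treat zeros as missing before transforming"
        )
    logged = matrix.intensities.copy()
    out = np.full_like(values, np.nan)
    np.log10(values, out=out, where=present)
    logged[:] = out
    return QuantMatrix(logged, scale="log10", precursor_counts=matrix.precursor_counts)


# -- sample metadata and marker panels ----------------------------------------

_SAMPLE_COLUMNS = ["sample_id", "workflow", "cell_type", "cell_count", "replicate", "group"]


def read_sample_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id",) if c not in table.columns]
    if missing:
        raise ValueError(f"sample table lacks required columns: {missing}")
    if table["sample_id"].duplicated().any():
        dups = sorted(table["sample_id"][table["sample_id"].duplicated()].tolist())
        raise ValueError(f"duplicate sample ids: {dups}")
    if "cell_count" in table.columns and (table["cell_count"].fillna(0) < 0).any():
        raise ValueError("cell_count must be nonnegative")
    return table


def write_sample_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in _SAMPLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(path, sep="\t", index=False)


_PANEL_COLUMNS = [
    "protein_id",
    "cell_type",
    "fold_change",
    "rank",
    "mean_log10_intensity",
    "cv",
    "exclusive",
]


def read_marker_panel_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "cell_type", "fold_change", "rank"):
        if col not in frame.columns:
            raise ValueError(f"marker panel file lacks column {col!r}")
    return frame


def write_marker_panel_frame(frame: pd.DataFrame, path) -> None:
    cols = [c for c in _PANEL_COLUMNS if c in frame.columns]
    frame.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- QC reports ----------------------------------------------------------------


def write_qc_report(report, out_dir) -> dict[str, Path]:
    """Write a :class:`plasmaqc.qc.QCReport` as JSON plus per-table TSVs.

    Output is deterministic (stable column order, no timestamps), so two
    writes of the same report are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema": QC_REPORT_SCHEMA,
        "parameters": report.parameters,
        "per_sample": report.per_sample.to_dict(orient="records"),
        "group_bias": report.group_bias.to_dict(orient="records"),
        "candidate_validation": report.candidate_validation.to_dict(orient="records"),
    }
    paths = {"json": out_dir / "qc_report.json"}
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    for name, table in (
        ("per_sample", report.per_sample),
        ("group_bias", report.group_bias),
        ("candidate_validation", report.candidate_validation),
    ):
        p = out_dir / f"qc_{name}.tsv"
        header_comment = f"# {QC_REPORT_SCHEMA}\n"
        with open(p, "w") as fh:
            fh.write(header_comment)
            table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        paths[name] = p
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
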
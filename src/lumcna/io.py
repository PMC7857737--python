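"""Input/output for CNA call matrices, clinical tables and expression-quantile labels.

All three formats are plain tab-delimited text:

* **CNA matrix** — cBioPortal ``data_CNA`` dialect: the first two columns are
  the gene symbol and the numeric gene id, followed by one column per sample.
  Calls are discrete copy-number states: homozygous deletion (−2), hemizygous
  deletion (−1), diploid (0), single-copy gain (+1), high-level amplification
  (+2).  Empty cells or ``NA`` are treated as missing and counted.
* **Clinical table** — one row per patient with overall-survival (OS) and
  disease-specific-survival (DSS) times in months plus event flags, the PAM50
  luminal subtype, and the usual clinico-pathological covariates.  Unknown
  columns are carried along as extra variables.
* **Quantile labels** — two columns mapping patient ids to the published
  expression-based quantile labels ``q1``–``q4``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lumcna")

VALID_CALLS = frozenset({-2, -1, 0, 1, 2})
QUANTILE_LEVELS = ("q1", "q2", "q3", "q4")
QUARTILE_LEVELS = ("Q1", "Q2", "Q3", "Q4")


class FormatError(ValueError):
    """Malformed input file (bad header, wrong column count)."""


class SchemaError(ValueError):
    """Clinical file does not satisfy the declared schema."""


# ---------------------------------------------------------------------------
# Clinical schema
# ---------------------------------------------------------------------------

#: Default clinical schema: required columns, their kinds and level sets.
#: ``categorical`` entries list the allowed levels in reference-first order.
DEFAULT_SCHEMA: dict = {
    "patient_id": {"kind": "id"},
    "os_months": {"kind": "time"},
    "os_event": {"kind": "event"},
    "dss_months": {"kind": "time"},
    "dss_event": {"kind": "event"},
    "pam50": {"kind": "categorical", "levels": ["lumA", "lumB"]},
    "grade": {"kind": "categorical", "levels": ["1", "2", "3"]},
    "tumour_size": {"kind": "continuous"},
    "positive_lymph_nodes": {"kind": "continuous"},
    "age_at_diagnosis": {"kind": "continuous"},
    "her2_status": {"kind": "categorical", "levels": ["negative", "positive"]},
}


def load_schema(path) -> dict:
    """Load a clinical schema from YAML, overlaying the defaults."""
    with open(path) as fh:
        overlay = yaml.safe_load(fh) or {}
    schema = {k: dict(v) for k, v in DEFAULT_SCHEMA.items()}
    for name, spec in overlay.items():
        schema[name] = dict(spec)
    return schema


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CnaMatrix:
    """Discrete gene × patient copy-number call matrix.

    ``calls`` is a float DataFrame (NaN marks a missing call) whose index is a
    (gene_symbol, gene_id) MultiIndex and whose columns are patient ids.
    Duplicate gene symbols are kept as distinct rows keyed by (symbol, id):
    collapsing them would silently change downstream burden scores.
    """

    calls: pd.DataFrame
    n_missing: int = 0

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float, copy=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            mn = np.nanmin(vals) if vals.size else 0.0
            mx = np.nanmax(vals) if vals.size else 0.0
        integral = np.array_equal(vals, np.floor(vals), equal_nan=True)
        if (np.isfinite(mn) and mn < -2) or (np.isfinite(mx) and mx > 2) or not integral:
            finite = vals[np.isfinite(vals)]
            bad = (np.abs(finite) > 2) | (finite != np.floor(finite))
            raise ValueError(
                f"CNA calls outside {{-2..+2}}: found {sorted(set(finite[bad]))[:5]}"
            )
        if self.calls.columns.duplicated().any():
            dupes = self.calls.columns[self.calls.columns.duplicated()].tolist()
            raise ValueError(f"duplicate patient ids in CNA matrix: {dupes[:5]}")
        if self.calls.index.duplicated().any():
            dupes = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValueError(f"duplicate (symbol, id) gene keys: {dupes[:5]}")

    @property
    def gene_ids(self) -> list:
        return list(self.calls.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_genes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_patients(self) -> int:
        return self.calls.shape[1]


@dataclass
class ClinicalTable:
    """Per-patient covariates plus (time, event) pairs for OS and DSS.

    ``data`` is indexed by patient id.  Declared categorical columns are
    stored as ordered pandas Categoricals whose first level is the model
    reference level.  Columns beyond the schema are preserved as extras.
    """

    data: pd.DataFrame
    schema: dict = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        validate_clinical(self.data, self.schema)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def extra_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.schema]

    def survival(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, events) for ``outcome`` in {"OS", "DSS"}."""
        key = outcome.lower()
        if key not in ("os", "dss"):
            raise ValueError(f"outcome must be 'OS' or 'DSS', got {outcome!r}")
        t = self.data[f"{key}_months"].to_numpy(dtype=float)
        e = self.data[f"{key}_event"].to_numpy(dtype=int)
        return t, e


@dataclass
class QuantileLabels:
    """Published expression-quantile labels (q1–q4) keyed by patient id."""

    labels: pd.Series  # index: patient_id, values: q1..q4

    def __post_init__(self) -> None:
        bad = set(self.labels.dropna().unique()) - set(QUANTILE_LEVELS)
        if bad:
            raise ValueError(f"unknown quantile labels: {sorted(bad)}")
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate patient ids in quantile labels")
        self.labels = pd.Series(
            pd.Categorical(self.labels, categories=list(QUANTILE_LEVELS), ordered=True),
            index=self.labels.index,
            name="tish_quantile",
        )

    @property
    def patient_ids(self) -> list[str]:
        return list(self.labels.index)


def validate_clinical(data: pd.DataFrame, schema: dict) -> None:
    missing = [
        c for c, spec in schema.items()
        if spec["kind"] != "id" and c not in data.columns
    ]
    if missing:
        raise SchemaError(f"missing required clinical columns: {missing}")
    if data.index.duplicated().any():
        raise SchemaError("duplicate patient ids in clinical table")
    for col, spec in schema.items():
        if col not in data.columns:
            continue
        kind = spec["kind"]
        vals = data[col]
        if kind == "time":
            arr = vals.to_numpy(dtype=float)
            if np.any(arr[np.isfinite(arr)] < 0):
                rows = data.index[np.nan_to_num(arr) < 0].tolist()
                raise ValueError(f"negative {col} for patients {rows[:5]}")
        elif kind == "event":
            arr = vals.dropna().unique()
            if not set(arr) <= {0, 1, 0.0, 1.0, True, False}:
                raise ValueError(f"{col} must be binary 0/1, got {sorted(arr)[:5]}")
        elif kind == "categorical":
            levels = [str(l) for l in spec["levels"]]
            observed = vals.dropna().astype(str)
            bad = ~observed.isin(levels)
            if bad.any():
                idx = observed.index[bad]
                row_pos = [data.index.get_loc(i) for i in idx[:5]]
                raise ValueError(
                    f"column {col!r}: values {sorted(set(observed[bad]))[:5]} outside "
                    f"declared levels {levels} (row indices {row_pos})"
                )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_cna_matrix(path, dialect: str = "cbioportal") -> CnaMatrix:
    """Read a discrete CNA call matrix in the cBioPortal ``data_CNA`` dialect.

    Out-of-range calls raise a :class:`ValueError` naming the offending gene
    and sample; missing cells (empty or ``NA``) are counted and logged.
    """
    if dialect != "cbioportal":
        raise ValueError(f"unknown CNA dialect: {dialect!r}")
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] < 3:
        raise FormatError(
            f"{path}: expected gene symbol, gene id and >=1 sample column, "
            f"got {raw.shape[1]} columns"
        )
    sym_col, id_col = raw.columns[:2]
    sample_cols = list(raw.columns[2:])
    index = pd.MultiIndex.from_arrays(
        [raw[sym_col].astype(str), raw[id_col].astype(str)],
        names=["gene_symbol", "gene_id"],
    )
    calls = np.full((len(raw), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        cell = raw[col].str.strip()
        is_missing = cell.isna() | (cell == "") | (cell.str.upper() == "NA")
        numeric = pd.to_numeric(cell.where(~is_missing), errors="coerce")
        bad = numeric.isna() & ~is_missing
        if bad.any():
            g = index[bad.idxmax()]
            raise ValueError(
                f"non-integer CNA call {cell[bad.idxmax()]!r} for gene {g[0]} "
                f"in sample {col}"
            )
        frac = numeric % 1
        if ((frac != 0) & numeric.notna()).any():
            g = index[(frac != 0).idxmax()]
            raise ValueError(
                f"non-integer CNA call for gene {g[0]} in sample {col}"
            )
        out_of_range = (numeric.abs() > 2) & numeric.notna()
        if out_of_range.any():
            g = index[out_of_range.idxmax()]
            raise ValueError(
                f"CNA call {numeric[out_of_range.idxmax()]:g} out of range "
                f"{{-2..+2}} for gene {g[0]} in sample {col}"
            )
        calls[:, j] = numeric.to_numpy(dtype=float)
    n_missing = int(np.isnan(calls).sum())
    if n_missing:
        logger.warning("%s: %d missing CNA calls (treated as 0 in scores)", path, n_missing)
        warnings.warn(f"{n_missing} missing CNA calls", stacklevel=2)
    frame = pd.DataFrame(calls, index=index, columns=sample_cols)
    return CnaMatrix(frame, n_missing=n_missing)


def write_cna_matrix(matrix: CnaMatrix, path) -> None:
    out = matrix.calls.copy()
    out.columns.name = None
    txt = out.map(lambda v: "NA" if not np.isfinite(v) else str(int(v)))
    txt.insert(0, "Entrez_Gene_Id", out.index.get_level_values("gene_id"))
    txt.insert(0, "Hugo_Symbol", out.index.get_level_values("gene_symbol"))
    txt.to_csv(path, sep="\t", index=False)


def read_clinical(path, schema: Mapping | None = None) -> ClinicalTable:
    """Read and validate a tab-delimited clinical annotation table."""
    schema = dict(schema) if schema is not None else DEFAULT_SCHEMA
    raw = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "patient_id" not in raw.columns:
        raise SchemaError(f"{path}: no patient_id column")
    raw = raw.set_index("patient_id")
    for col, spec in schema.items():
        if col not in raw.columns:
            continue
        if spec["kind"] == "categorical":
            levels = [str(l) for l in spec["levels"]]
            observed = raw[col].astype(str).where(raw[col].notna())
            bad = observed.dropna()[~observed.dropna().isin(levels)]
            if len(bad):
                pos = [raw.index.get_loc(i) for i in bad.index[:5]]
                raise ValueError(
                    f"{path}: column {col!r} has values {sorted(set(bad))[:5]} outside "
                    f"levels {levels} at row indices {pos}"
                )
            raw[col] = pd.Categorical(observed, categories=levels, ordered=True)
        elif spec["kind"] in ("time", "continuous"):
            raw[col] = pd.to_numeric(raw[col], errors="raise")
        elif spec["kind"] == "event":
            raw[col] = pd.to_numeric(raw[col], errors="raise").astype("Int64")
    return ClinicalTable(raw, schema=schema)


def write_clinical(table: ClinicalTable, path) -> None:
    out = table.data.copy()
    out.insert(0, "patient_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_quantile_labels(path) -> QuantileLabels:
    """Read a two-column patient-id → q1..q4 label file."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns, got {raw.shape[1]}")
    raw.columns = ["patient_id", "tish_quantile"]
    labels = raw.set_index("patient_id")["tish_quantile"].str.strip()
    return QuantileLabels(labels)


def write_quantile_labels(labels: QuantileLabels, path) -> None:
    out = labels.labels.rename("tish_quantile").to_frame()
    out.insert(0, "patient_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def join_labels(clinical: ClinicalTable, labels: QuantileLabels) -> pd.DataFrame:
    """Inner-join quantile labels onto a clinical table on patient id.

    Only shared patients are kept; the intersection size (and the number of
    ids dropped from either side) is logged.
    """
    shared = clinical.data.index.intersection(labels.labels.index)
    logger.info(
        "label join: %d shared patients (%d clinical-only, %d label-only)",
        len(shared),
        len(clinical.data.index.difference(labels.labels.index)),
        len(labels.labels.index.difference(clinical.data.index)),
    )
    joined = clinical.data.loc[shared].copy()
    joined["tish_quantile"] = labels.labels.loc[shared]
    joined.attrs["n_intersection"] = len(shared)
    return joined
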
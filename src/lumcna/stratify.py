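"""Cross-stratification of CNA quartiles against expression quantiles.

Relates the genomic-instability quartiles Q1-Q4 to the published
expression-based quantile labels q1-q4 over the patients the two tables
share, optionally within a clinical subset (e.g. luminal A only), and
summarises the overlap of chosen high-risk blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QUANTILE_LEVELS, QUARTILE_LEVELS, ClinicalTable, QuantileLabels
from .assoc import ContingencyTable
from .cna_score import ScoreTable

logger = logging.getLogger("lumcna")


@dataclass
class CrossTab:
    """Quartile x quantile contingency table over the id intersection."""

    table: ContingencyTable  # rows: tish_quantile q1..q4, cols: quartile Q1..Q4
    n_intersection: int

    @property
    def counts(self) -> pd.DataFrame:
        return self.table.counts

    @property
    def total(self) -> int:
        return self.table.total

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = out.sum(axis=1)
        out.loc["Total"] = out.sum(axis=0)
        return out

    def write(self, path) -> None:
        out = self.with_margins()
        out.insert(0, out.index.name or "tish_quantile", out.index)
        out.to_csv(path, sep="\t", index=False)


def crosstab(
    score: ScoreTable,
    labels: QuantileLabels,
    clinical: ClinicalTable | None = None,
    subset: pd.Series | None = None,
) -> CrossTab:
    """Tabulate quartile membership against expression-quantile labels.

    Counts are over the patient-id intersection of the two tables; patients
    present on only one side are dropped and logged.  ``subset`` (a boolean
    Series indexed by patient id, e.g. ``clinical.data["pam50"] == "lumA"``)
    restricts the tabulation.
    """
    if score.table.empty or labels.labels.empty:
        raise ValueError("empty score table or label table")
    shared = score.table.index.intersection(labels.labels.index)
    if subset is not None:
        shared = shared.intersection(subset.index[subset.astype(bool)])
    if len(shared) == 0:
        raise ValueError("no patients shared between score table and labels")
    dropped = (len(score.table) - len(shared)) + (len(labels.labels) - len(shared))
    logger.info("crosstab: %d shared patients (%d ids dropped)", len(shared), dropped)
    quart = score.quartiles.loc[shared].astype(str)
    quant = labels.labels.loc[shared].astype(str)
    tab = ContingencyTable.from_arrays(
        quant, quart, row_labels=QUANTILE_LEVELS, col_labels=QUARTILE_LEVELS
    )
    tab.counts.index.name = "tish_quantile"
    tab.counts.columns.name = "quartile"
    return CrossTab(tab, n_intersection=len(shared))


def high_risk_overlap(
    xtab: CrossTab, quartile_set, quantile_set
) -> tuple[int, float]:
    """Count and fraction of patients in a quartile x quantile block."""
    unknown_q = set(quartile_set) - set(QUARTILE_LEVELS)
    unknown_t = set(quantile_set) - set(QUANTILE_LEVELS)
    if unknown_q or unknown_t:
        raise ValueError(f"unknown labels: {sorted(unknown_q | unknown_t)}")
    if not quartile_set or not quantile_set:
        return 0, 0.0
    block = xtab.counts.loc[sorted(quantile_set), sorted(quartile_set)]
    count = int(block.to_numpy().sum())
    return count, count / xtab.total


def score_by_quantile_summary(
    score: ScoreTable, labels: QuantileLabels
) -> pd.DataFrame:
    """Per-quantile CNA Score summary (the tabular face of the violin plot)."""
    shared = score.table.index.intersection(labels.labels.index)
    frame = pd.DataFrame(
        {
            "cna_score": score.scores.loc[shared],
            "tish_quantile": labels.labels.loc[shared].astype(str),
        }
    )
    return (
        frame.groupby("tish_quantile")["cna_score"]
        .agg(["count", "median", "mean", "min", "max"])
        .reset_index()
    )
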
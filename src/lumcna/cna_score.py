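"""Per-patient CNA burden scores and ranked quartile segmentation.

The CNA Score of a patient is the sum of the absolute values of the discrete
copy-number calls over all genes — a first-order genomic-instability metric
that deliberately ignores segment length, direction (gain vs loss) and genomic
location.  Patients are then segmented into ranked quartiles Q1–Q4 of the
score distribution; Q4 is the most genomically unstable quarter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QUARTILE_LEVELS, CnaMatrix


@dataclass
class ScoreTable:
    """Per-patient CNA Score, quartile label and the quartile thresholds.

    ``thresholds`` holds the empirical 25th/50th/75th percentile scores
    (lower order statistic, so thresholds are attained score values); a
    patient is in Q1 if score <= t1, Q2 if t1 < score <= t2, and so on.
    """

    table: pd.DataFrame  # index patient_id; columns cna_score, quartile
    thresholds: tuple | None = None

    @property
    def scores(self) -> pd.Series:
        return self.table["cna_score"]

    @property
    def quartiles(self) -> pd.Series:
        return self.table["quartile"]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)


def compute_cna_scores(cna: CnaMatrix) -> ScoreTable:
    """Sum |call| over all genes for each patient; missing calls add 0."""
    if cna.n_patients == 0:
        raise ValueError("CNA matrix has no patients")
    vals = cna.calls.to_numpy(dtype=float)
    scores = np.nansum(np.abs(vals), axis=0).astype(int)
    table = pd.DataFrame({"cna_score": scores}, index=pd.Index(cna.patient_ids, name="patient_id"))
    return ScoreTable(table)


def quartile_thresholds(scores: np.ndarray) -> tuple:
    """Empirical 25/50/75 percentiles as lower order statistics (type 1).

    t_k = x_(ceil(k*n/4)) on the sorted scores, so each threshold is an
    attained score and the quartile rule stays integer-valued.
    """
    x = np.sort(np.asarray(scores))
    n = len(x)
    idx = [int(np.ceil(k * n / 4.0)) - 1 for k in (1, 2, 3)]
    return tuple(x[i] for i in idx)


def assign_quartiles(score_table: ScoreTable) -> ScoreTable:
    """Assign ranked quartiles Q1–Q4 from the empirical score distribution.

    Ties at a threshold fall into the lower quartile (the thresholds are
    attained values and the rule is score <= t_k).  If every score is equal
    the whole cohort lands in Q1 and a warning is emitted.
    """
    scores = score_table.scores.to_numpy()
    if len(scores) < 4:
        raise ValueError(f"need >= 4 patients to form quartiles, got {len(scores)}")
    t1, t2, t3 = quartile_thresholds(scores)
    if t1 == t3:
        warnings.warn(
            "degenerate score distribution: quartile thresholds coincide", stacklevel=2
        )
    labels = np.select(
        [scores <= t1, scores <= t2, scores <= t3],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    table = score_table.table.copy()
    table["quartile"] = pd.Categorical(
        labels, categories=list(QUARTILE_LEVELS), ordered=True
    )
    return ScoreTable(table, thresholds=(t1, t2, t3))


def score_and_quartile(cna: CnaMatrix) -> ScoreTable:
    """Convenience: compute scores then assign quartiles."""
    return assign_quartiles(compute_cna_scores(cna))


def write_score_table(score: ScoreTable, path) -> None:
    out = score.table.copy()
    out.insert(0, "patient_id", out.index)
    out.to_csv(path, sep="\t", index=False)
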
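"""Confounder association battery and survival-variable screening.

Categorical-vs-categorical associations use the Pearson chi-square test when
expected cell counts allow, falling back to Fisher's exact test (exact for
2x2, margin-preserving Monte Carlo for larger tables) when any expected count
is small.  Continuous-vs-quartile associations use the Kruskal-Wallis rank
test.  Variable screening against survival uses the log-rank test for
categorical variables and a univariate Cox Wald test for continuous ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import survkit

#: Expected-count threshold below which a table routes to Fisher's test.
SMALL_CELL_EXPECTED = 5.0
DEFAULT_ALPHA = 0.05
DEFAULT_MC_REPS = 10_000


@dataclass
class ContingencyTable:
    """Two-way table of counts with labelled axes."""

    counts: pd.DataFrame  # rows x cols, non-negative integers

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts in contingency table")

    @classmethod
    def from_arrays(cls, rows, cols, row_labels=None, col_labels=None) -> "ContingencyTable":
        tab = pd.crosstab(pd.Series(rows, name="row"), pd.Series(cols, name="col"))
        if row_labels is not None:
            tab = tab.reindex(index=list(row_labels), fill_value=0)
        if col_labels is not None:
            tab = tab.reindex(columns=list(col_labels), fill_value=0)
        return cls(tab)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def expected(self) -> np.ndarray:
        n = self.total
        return np.outer(self.row_margins, self.col_margins) / n


def chi_square_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test without continuity correction."""
    counts = table.counts.to_numpy(dtype=float)
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        raise ValueError(
            "zero row/column margin: collapse empty categories before testing"
        )
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def fisher_exact_test(
    table: ContingencyTable, mc_reps: int = DEFAULT_MC_REPS, seed: int = 0
) -> float:
    """Two-sided Fisher's exact test.

    2x2 tables are exact (sum of hypergeometric probabilities no larger than
    the observed table's).  Larger tables use Monte-Carlo sampling of tables
    with the observed margins (Patefield's algorithm via
    ``scipy.stats.random_table``) and the add-one p-value correction
    (1 + #{as extreme}) / (reps + 1).
    """
    counts = table.counts.to_numpy(dtype=int)
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        # a degenerate margin carries no information against independence
        return 1.0
    if counts.shape == (2, 2):
        _, p = stats.fisher_exact(counts, alternative="two-sided")
        return float(p)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.row_margins, table.col_margins)
    logp_obs = dist.logpmf(counts)
    samples = dist.rvs(size=mc_reps, method="patefield", random_state=rng)
    logp_samp = dist.logpmf(samples)
    n_extreme = int(np.sum(logp_samp <= logp_obs + 1e-9))
    return float((1 + n_extreme) / (mc_reps + 1))


def kruskal_wallis_test(values, group_labels) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction (chi-square p, k-1 df)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    groups = [v[g == lvl] for lvl in pd.unique(g)]
    groups = [grp for grp in groups if grp.size > 0]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    if np.ptp(v) == 0:
        warnings.warn("all values identical: Kruskal-Wallis undefined, p = 1", stacklevel=2)
        return float("nan"), len(groups) - 1, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), len(groups) - 1, float(p)


@dataclass
class ScreeningReport:
    """Per-variable screening results against one survival outcome."""

    outcome: str
    results: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: variable, test, statistic, p, selected
    alpha: float = DEFAULT_ALPHA

    @property
    def selected(self) -> list[str]:
        if self.results.empty:
            return []
        return self.results.loc[self.results["selected"], "variable"].tolist()

    def write(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)


def _is_categorical(series: pd.Series) -> bool:
    return isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == object


def screen_survival_variables(
    clinical,
    outcome: str = "OS",
    alpha: float = DEFAULT_ALPHA,
    variables: list[str] | None = None,
) -> ScreeningReport:
    """Screen clinical variables for association with a survival outcome.

    Categorical variables use the log-rank test across their levels;
    continuous variables use the Wald test of a univariate Cox model.
    A variable is selected when p < alpha.
    """
    if outcome.upper() not in ("OS", "DSS"):
        raise ValueError("outcome must be 'OS' or 'DSS'")
    frame = clinical.data
    t, e = clinical.survival(outcome)
    reserved = {"os_months", "os_event", "dss_months", "dss_event"}
    if variables is None:
        variables = [c for c in frame.columns if c not in reserved]
    rows = []
    for var in variables:
        s = frame[var]
        mask = s.notna() & np.isfinite(t) & (t >= 0)
        sv, tv, ev = s[mask], t[mask.to_numpy()], e[mask.to_numpy()]
        try:
            if _is_categorical(s):
                if sv.astype(str).nunique() < 2:
                    warnings.warn(f"{var}: single observed level, skipped", stacklevel=2)
                    continue
                res = survkit.logrank_test(tv, ev, sv.astype(str).to_numpy())
                test, statistic, p = "logrank", res.statistic, res.p_value
            else:
                if np.ptp(sv.to_numpy(dtype=float)) == 0:
                    warnings.warn(f"{var}: constant variable, skipped", stacklevel=2)
                    continue
                fit = survkit.cox_fit(sv.to_numpy(dtype=float)[:, None], tv, ev)
                test, statistic = "cox_wald", float(fit.z[0] ** 2)
                p = float(fit.p_values[0])
        except ValueError as exc:
            warnings.warn(f"{var}: {exc}; skipped", stacklevel=2)
            continue
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": statistic,
                "p": p,
                "selected": bool(p < alpha),
            }
        )
    return ScreeningReport(outcome=outcome.upper(), results=pd.DataFrame(rows), alpha=alpha)


def screen_confounders(
    clinical,
    score,
    alpha: float = DEFAULT_ALPHA,
    variables: list[str] | None = None,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int = 0,
) -> ScreeningReport:
    """Test each variable for association with the CNA quartile grouping.

    Categorical variables: chi-square, or Fisher's exact test when any
    expected cell count is below 5.  Continuous variables: Kruskal-Wallis.
    """
    frame = clinical.data
    shared = frame.index.intersection(score.table.index)
    frame = frame.loc[shared]
    quart = score.quartiles.loc[shared].astype(str).to_numpy()
    reserved = {"os_months", "os_event", "dss_months", "dss_event"}
    if variables is None:
        variables = [c for c in frame.columns if c not in reserved]
    rows = []
    for var in variables:
        s = frame[var]
        mask = s.notna()
        sv, qv = s[mask], quart[mask.to_numpy()]
        try:
            if _is_categorical(s):
                tab = ContingencyTable.from_arrays(qv, sv.astype(str).to_numpy())
                # drop empty rows/cols before the expected-count rule
                keep_r = tab.counts.sum(axis=1) > 0
                keep_c = tab.counts.sum(axis=0) > 0
                tab = ContingencyTable(tab.counts.loc[keep_r, keep_c])
                if min(tab.counts.shape) < 2:
                    warnings.warn(f"{var}: single observed level, skipped", stacklevel=2)
                    continue
                if (tab.expected() < SMALL_CELL_EXPECTED).any():
                    p = fisher_exact_test(tab, mc_reps=mc_reps, seed=seed)
                    test, statistic = "fisher", float("nan")
                else:
                    statistic, _, p = chi_square_test(tab)
                    test = "chi_square"
            else:
                statistic, _, p = kruskal_wallis_test(
                    sv.to_numpy(dtype=float), qv
                )
                test = "kruskal_wallis"
        except ValueError as exc:
            warnings.warn(f"{var}: {exc}; skipped", stacklevel=2)
            continue
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": statistic,
                "p": p,
                "selected": bool(p < alpha),
            }
        )
    return ScreeningReport(outcome="quartile", results=pd.DataFrame(rows), alpha=alpha)
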
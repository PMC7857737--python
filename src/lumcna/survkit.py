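"""From-scratch survival machinery.

Implements the estimators the analysis rests on, with no survival-package
dependency (lifelines / scikit-survival appear only as independent oracles in
the test suite):

* Kaplan–Meier product-limit curves and median survival with a
  ``not reached`` sentinel;
* the k-group log-rank test with hypergeometric variance;
* Cox proportional-hazards regression by Newton–Raphson on the partial
  likelihood, Efron tie correction by default (Breslow available), with
  likelihood-ratio, Wald and score tests and the Breslow baseline cumulative
  hazard;
* treatment-coded design matrices with interactions from a tiny formula
  language (``"a + b + a:b"``);
* covariate-adjusted survival curves for arbitrary covariate profiles;
* proportional-hazards diagnostics from scaled Schoenfeld residuals against
  the ``1 − KM(t)`` time transform.

Times are months throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Newton-Raphson controls: relative log-likelihood tolerance, iteration cap,
# and the |beta| beyond which monotone likelihood (separation) is flagged.
NR_TOL = 1e-9
NR_MAX_ITER = 50
SEPARATION_BETA = 20.0

Z_95 = 1.959964  # two-sided 95% normal quantile, as used in reported CIs


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the final gradient norm."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function with risk counts.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S = 1 before the
    first event time.  ``at_risk[i]`` counts subjects with follow-up
    >= ``event_times[i]``.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: np.ndarray | None = None

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or array t (step-function lookup)."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if np.ndim(t) else float(out[0])


def _check_surv_input(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event indicators must be 0/1")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    t, e = _check_surv_input(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    # at risk: subjects with follow-up >= each event time
    n_at_risk = t.size - np.searchsorted(t, event_times, side="left")
    d = np.array([int(e[t == u].sum()) for u in event_times])
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    return SurvivalCurve(event_times, surv, n_at_risk, n=t.size, n_events=d)


NOT_REACHED = None  # sentinel for a median outside the observed range


def median_survival(curve: SurvivalCurve):
    """Smallest event time with S(t) <= 0.5, or None if never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(curve.event_times[below[0]])


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray | None = None
    expected: np.ndarray | None = None


def logrank_test(times, events, group_labels) -> LogRankResult:
    """k-group log-rank test (O - E with hypergeometric variance)."""
    t, e = _check_surv_input(times, events)
    g = np.asarray(group_labels)
    if g.shape != t.shape:
        raise ValueError("group labels must match times in length")
    groups = np.unique(g)
    k = groups.size
    if k < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    gidx = np.searchsorted(groups, g)
    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = t >= u
        n_j = int(at_risk.sum())
        dead = (t == u) & (e == 1)
        d_j = int(dead.sum())
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gidx[dead], minlength=k).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            c = d_j * (n_j - d_j) / (n_j - 1.0)
            p = n_gj / n_j
            V += c * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    # pinv guards the degenerate case of a group with no at-risk overlap
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p_value = float(stats.chi2.sf(stat, df))
    return LogRankResult(stat, df, p_value, observed=O, expected=E)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


class FormulaError(ValueError):
    """Formula references an unknown variable."""


def _marginal_columns(frame: pd.DataFrame, var: str) -> pd.DataFrame:
    """Columns for one variable: treatment dummies or the column itself."""
    if var not in frame.columns:
        raise FormulaError(f"unknown variable in formula: {var!r}")
    col = frame[var]
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        levels = (
            list(col.cat.categories)
            if isinstance(col.dtype, pd.CategoricalDtype)
            else sorted(col.dropna().unique())
        )
        out = pd.DataFrame(index=frame.index)
        for level in levels[1:]:  # first level is the reference
            out[f"{var}[{level}]"] = (col.astype(object) == level).astype(float)
        return out
    return pd.DataFrame({var: col.astype(float)}, index=frame.index)


def design_from_frame(frame: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Treatment-coded design matrix from ``"a + b + a:b"`` style formulas.

    Categorical variables contribute one dummy per non-reference level
    (reference = first declared level); ``a:b`` contributes the elementwise
    products of the two marginal column blocks.
    """
    terms = [term.strip() for term in formula.split("+") if term.strip()]
    blocks: list[pd.DataFrame] = []
    for term in terms:
        if ":" in term:
            left, right = (s.strip() for s in term.split(":", 1))
            lcols = _marginal_columns(frame, left)
            rcols = _marginal_columns(frame, right)
            inter = pd.DataFrame(index=frame.index)
            for lc in lcols.columns:
                for rc in rcols.columns:
                    inter[f"{lc}:{rc}"] = lcols[lc] * rcols[rc]
            blocks.append(inter)
        else:
            blocks.append(_marginal_columns(frame, term))
    design = pd.concat(blocks, axis=1)
    if design.columns.duplicated().any():
        design = design.loc[:, ~design.columns.duplicated()]
    return design


def build_design(clinical, score, formula: str) -> pd.DataFrame:
    """Join clinical covariates with CNA score/quartile and build the design.

    ``clinical`` is a :class:`lumcna.io.ClinicalTable`, ``score`` a
    :class:`lumcna.cna_score.ScoreTable` (or None if the formula does not use
    score variables).  Rows are restricted to patients present in both.
    """
    frame = clinical.data
    if score is not None:
        shared = frame.index.intersection(score.table.index)
        frame = frame.loc[shared].join(score.table.loc[shared])
    return design_from_frame(frame, formula)


#: The final multivariable model: clinical covariates, CNA quartile and the
#: quartile-by-subtype interaction (13 design columns).
PAPER_FORMULA = (
    "pam50 + grade + tumour_size + positive_lymph_nodes + age_at_diagnosis"
    " + her2_status + quartile + quartile:pam50"
)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    terms: list[str]
    beta: np.ndarray
    covariance: np.ndarray
    loglik_null: float
    loglik_fit: float
    lr_test: tuple  # (statistic, df, p)
    wald_test: tuple
    score_test: tuple
    ties_method: str
    baseline_times: np.ndarray  # unique event times
    baseline_cumhazard: np.ndarray  # Breslow H0 at those times (design x = 0)
    n: int
    n_events: int
    n_iter: int
    # retained data for diagnostics / adjusted curves (sorted by time)
    _times: np.ndarray = field(default=None, repr=False)
    _events: np.ndarray = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - Z_95 * self.se)
        hi = np.exp(self.beta + Z_95 * self.se)
        return np.column_stack([lo, hi])

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p_values,
            },
            index=pd.Index(self.terms, name="term"),
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "covariance": self.covariance.tolist(),
            "hr": self.hr.tolist(),
            "ci95": self.ci95.tolist(),
            "p_values": self.p_values.tolist(),
            "loglik_null": self.loglik_null,
            "loglik_fit": self.loglik_fit,
            "lr_test": list(self.lr_test),
            "wald_test": list(self.wald_test),
            "score_test": list(self.score_test),
            "ties_method": self.ties_method,
            "n": self.n,
            "n_events": self.n_events,
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhazard": self.baseline_cumhazard.tolist(),
        }


def _efron_quantities(t, e, X, beta, ties_method):
    """Log partial likelihood, score vector and observed information.

    Inputs are sorted ascending by time.  Returns (ll, U, I).
    """
    n, p = X.shape
    lp = X @ beta
    w = np.exp(lp)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # suffix sums over the risk set {i : t_i >= t_j}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    event_idx = np.nonzero(e == 1)[0]
    if event_idx.size == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    ev_times = t[event_idx]
    # tie groups: runs of equal event times
    group_starts = np.nonzero(np.r_[True, np.diff(ev_times) > 0])[0]
    group_ends = np.r_[group_starts[1:], ev_times.size]
    for a, b in zip(group_starts, group_ends):
        members = event_idx[a:b]
        d = b - a
        tj = ev_times[a]
        r0 = np.searchsorted(t, tj, side="left")  # first index in risk set
        s0r, s1r, s2r = S0[r0], S1[r0], S2[r0]
        if ties_method == "efron":
            frac = np.arange(d) / d
        else:  # breslow
            frac = np.zeros(d)
        s0d = w[members].sum()
        s1d = wX[members].sum(axis=0)
        s2d = wXX[members].sum(axis=0)
        denom = s0r - frac * s0d  # (d,)
        a1 = s1r[None, :] - frac[:, None] * s1d[None, :]  # (d, p)
        zbar = a1 / denom[:, None]
        ll += float(lp[members].sum() - np.log(denom).sum())
        U += X[members].sum(axis=0) - zbar.sum(axis=0)
        a2 = (s2r[None] - frac[:, None, None] * s2d[None]) / denom[:, None, None]
        I += (a2 - zbar[:, :, None] * zbar[:, None, :]).sum(axis=0)
    return ll, U, I


def cox_fit(design, times, events, ties_method: str = "efron") -> CoxFit:
    """Fit a Cox PH model by Newton-Raphson on the partial likelihood.

    ``design`` is a DataFrame (or array) of covariate columns; Efron's tie
    correction is the default, Breslow is available for oracle identities.
    The covariance is the inverse observed information at the maximum and the
    baseline cumulative hazard is the Breslow estimator referenced to a
    design row of zeros.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties_method!r}")
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns)
        Xraw = design.to_numpy(dtype=float)
    else:
        Xraw = np.asarray(design, dtype=float)
        if Xraw.ndim == 1:
            Xraw = Xraw[:, None]
        terms = [f"x{i}" for i in range(Xraw.shape[1])]
    t, e = _check_surv_input(times, events)
    if Xraw.shape[0] != t.size:
        raise ValueError("design and survival input lengths differ")
    if int(e.sum()) < 1:
        raise ValueError("at least one event is required")
    if np.linalg.matrix_rank(Xraw - Xraw.mean(axis=0)) < Xraw.shape[1]:
        raise ValueError("design columns are linearly dependent")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    # centre columns for numerical stability; the partial likelihood is
    # exactly invariant to covariate shifts so beta and its covariance are
    # unchanged, only the baseline hazard reference moves (undone below).
    mu = Xraw.mean(axis=0)
    X = Xraw[order] - mu

    p = X.shape[1]
    beta = np.zeros(p)
    ll0, U0, I0 = _efron_quantities(t, e, X, beta, ties_method)
    score_stat = float(U0 @ np.linalg.solve(I0, U0))
    ll_prev, U, I = ll0, U0, I0
    n_iter = 0
    for n_iter in range(1, NR_MAX_ITER + 1):
        step = np.linalg.solve(I, U)
        # step-halving on non-increase of the partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, U_new, I_new = _efron_quantities(t, e, X, cand, ties_method)
            if ll_new >= ll_prev - 1e-12:
                break
            factor /= 2.0
        beta, ll_cur, U, I = cand, ll_new, U_new, I_new
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            warnings.warn(
                "monotone partial likelihood: a coefficient is diverging "
                "(possible separation)",
                stacklevel=2,
            )
            break
        if abs(ll_cur - ll_prev) <= NR_TOL * (abs(ll_prev) + 0.1):
            ll_prev = ll_cur
            break
        ll_prev = ll_cur
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {NR_MAX_ITER} iterations; "
            f"|gradient| = {np.linalg.norm(U):.3g}"
        )

    ll_hat = ll_prev
    cov = np.linalg.inv(I)
    lr_stat = 2.0 * (ll_hat - ll0)
    wald_stat = float(beta @ I @ beta)
    df = p
    lr = (float(lr_stat), df, float(stats.chi2.sf(lr_stat, df)))
    wald = (wald_stat, df, float(stats.chi2.sf(wald_stat, df)))
    score = (score_stat, df, float(stats.chi2.sf(score_stat, df)))

    # Breslow baseline cumulative hazard at beta-hat, referenced to x = 0 of
    # the ORIGINAL (uncentred) design.
    w = np.exp(X @ beta)
    S0 = np.cumsum(w[::-1])[::-1]
    ev_times = np.unique(t[e == 1])
    increments = []
    for tj in ev_times:
        r0 = np.searchsorted(t, tj, side="left")
        d = int(((t == tj) & (e == 1)).sum())
        increments.append(d / S0[r0])
    H0_centered = np.cumsum(increments)
    H0 = H0_centered * np.exp(-float(mu @ beta))

    return CoxFit(
        terms=terms,
        beta=beta,
        covariance=cov,
        loglik_null=ll0,
        loglik_fit=ll_hat,
        lr_test=lr,
        wald_test=wald,
        score_test=score,
        ties_method=ties_method,
        baseline_times=ev_times,
        baseline_cumhazard=np.asarray(H0),
        n=t.size,
        n_events=int(e.sum()),
        n_iter=n_iter,
        _times=t,
        _events=e,
        _X=X,
    )


def fit_cox_model(
    clinical,
    score,
    formula: str = PAPER_FORMULA,
    outcome: str = "DSS",
    ties_method: str = "efron",
) -> CoxFit:
    """Build the design from clinical + score tables and fit the Cox model."""
    design = build_design(clinical, score, formula)
    frame = clinical.data.loc[design.index]
    t = frame[f"{outcome.lower()}_months"].to_numpy(dtype=float)
    e = frame[f"{outcome.lower()}_event"].to_numpy(dtype=int)
    return cox_fit(design, t, e, ties_method=ties_method)


def reparametrize_reference(
    clinical,
    score,
    variable: str,
    new_reference: str,
    formula: str = PAPER_FORMULA,
    outcome: str = "DSS",
    ties_method: str = "efron",
) -> CoxFit:
    """Refit with ``new_reference`` as the reference level of ``variable``.

    The fitted log-likelihood is invariant; contrasts within the new
    reference stratum (e.g. quartile effects within lumB) become main
    effects of the reparametrized model.
    """
    import copy

    clin = copy.copy(clinical)
    clin = type(clinical)(clinical.data.copy(), schema=clinical.schema)
    frame = clin.data
    sc = score
    if variable in frame.columns:
        col = frame[variable]
        if not isinstance(col.dtype, pd.CategoricalDtype):
            raise ValueError(f"{variable!r} is not categorical")
        levels = list(col.cat.categories)
        if new_reference not in levels:
            raise ValueError(f"{new_reference!r} not a level of {variable!r}")
        new_levels = [new_reference] + [l for l in levels if l != new_reference]
        frame[variable] = col.cat.reorder_categories(new_levels, ordered=True)
    elif sc is not None and variable in sc.table.columns:
        from .cna_score import ScoreTable

        tab = sc.table.copy()
        col = tab[variable]
        levels = list(col.cat.categories)
        if new_reference not in levels:
            raise ValueError(f"{new_reference!r} not a level of {variable!r}")
        new_levels = [new_reference] + [l for l in levels if l != new_reference]
        tab[variable] = col.cat.reorder_categories(new_levels, ordered=True)
        sc = ScoreTable(tab, thresholds=sc.thresholds)
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return fit_cox_model(clin, sc, formula=formula, outcome=outcome, ties_method=ties_method)


def linear_contrast(fit: CoxFit, weights: Mapping[str, float]) -> tuple:
    """Estimate, SE and Wald p for a linear combination of coefficients."""
    c = np.zeros(len(fit.terms))
    for name, wgt in weights.items():
        if name not in fit.terms:
            raise ValueError(f"unknown term {name!r}")
        c[fit.terms.index(name)] = wgt
    est = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.covariance @ c))
    pval = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else float("nan")
    return est, se, pval


# ---------------------------------------------------------------------------
# Adjusted survival curves
# ---------------------------------------------------------------------------


def median_mode_profile(frame: pd.DataFrame, exclude: Sequence[str] = ()) -> dict:
    """Median for quantitative variables, mode for categorical ones."""
    profile: dict = {}
    for col in frame.columns:
        if col in exclude:
            continue
        s = frame[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            profile[col] = s.mode(dropna=True).iloc[0]
        elif np.issubdtype(np.asarray(s).dtype, np.number):
            profile[col] = float(s.median())
    return profile


def adjusted_survival_curves(
    fit: CoxFit,
    profiles: Mapping[str, Mapping],
    formula: str,
    template: pd.DataFrame,
) -> dict[str, SurvivalCurve]:
    """Model-based survival curves S(t|x) = exp(-H0(t) exp(lp(x))).

    ``profiles`` maps a label to a complete covariate dict (every variable in
    the formula must be supplied — typically medians/modes with the stratum
    variable overridden).  ``template`` is the fitting frame, used to carry
    categorical level declarations into the one-row designs.
    """
    out: dict[str, SurvivalCurve] = {}
    formula_vars = {
        v.strip()
        for term in formula.split("+")
        for v in term.strip().split(":")
        if v.strip()
    }
    for label, profile in profiles.items():
        missing = formula_vars - set(profile)
        if missing:
            raise ValueError(f"profile {label!r} missing covariates: {sorted(missing)}")
        row = {}
        for col in template.columns:
            if col in profile:
                row[col] = [profile[col]]
        frame = pd.DataFrame(row, index=["profile"])
        for col in frame.columns:
            if isinstance(template[col].dtype, pd.CategoricalDtype):
                frame[col] = pd.Categorical(
                    frame[col],
                    categories=template[col].cat.categories,
                    ordered=True,
                )
        design_row = design_from_frame(frame, formula)
        design_row = design_row.reindex(columns=fit.terms, fill_value=0.0)
        lp = float((design_row.to_numpy(dtype=float) @ fit.beta)[0])
        surv = np.exp(-fit.baseline_cumhazard * np.exp(lp))
        at_risk = fit.n - np.searchsorted(fit._times, fit.baseline_times, side="left")
        out[label] = SurvivalCurve(
            fit.baseline_times.copy(), surv, at_risk, n=fit.n
        )
    return out


def baseline_survival(fit: CoxFit) -> SurvivalCurve:
    """Survival curve of the reference profile (linear predictor 0)."""
    surv = np.exp(-fit.baseline_cumhazard)
    at_risk = fit.n - np.searchsorted(fit._times, fit.baseline_times, side="left")
    return SurvivalCurve(fit.baseline_times.copy(), surv, at_risk, n=fit.n)


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PhDiagnostics:
    """Scaled-Schoenfeld tests of the proportional-hazards assumption."""

    terms: list[str]
    correlations: np.ndarray  # per-term corr(g(t), scaled residual)
    term_statistics: np.ndarray
    term_p_values: np.ndarray
    global_statistic: float
    global_df: int
    global_p_value: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rho": self.correlations,
                "chisq": self.term_statistics,
                "p": self.term_p_values,
            },
            index=pd.Index(self.terms, name="term"),
        )


def schoenfeld_residuals(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-event Schoenfeld residuals x_i - xbar(t_i) and the event times."""
    t, e, X = fit._times, fit._events, fit._X
    w = np.exp(X @ fit.beta)
    wX = w[:, None] * X
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    event_idx = np.nonzero(e == 1)[0]
    times = t[event_idx]
    resid = np.empty((event_idx.size, X.shape[1]))
    for row, i in enumerate(event_idx):
        r0 = np.searchsorted(t, t[i], side="left")
        resid[row] = X[i] - S1[r0] / S0[r0]
    return resid, times


def ph_diagnostics(fit: CoxFit) -> PhDiagnostics:
    """Grambsch-Therneau tests from scaled Schoenfeld residuals.

    The time transform is g(t) = 1 - KM(t) with KM the all-cohort
    Kaplan-Meier estimate (left limit at each event time); per-term and
    global chi-square statistics follow the standard approximation with the
    average residual variance I / d.
    """
    if fit.n_events < 2:
        raise ValueError("PH diagnostics need at least 2 events")
    resid, times = schoenfeld_residuals(fit)
    d = resid.shape[0]
    km = km_estimate(fit._times, fit._events)
    # left-continuous KM at each event time (value just before t)
    idx = np.searchsorted(km.event_times, times, side="left") - 1
    km_left = np.where(idx < 0, 1.0, km.survival[np.clip(idx, 0, None)])
    g = 1.0 - km_left
    gc = g - g.mean()
    sum_g2 = float(gc @ gc)
    I = np.linalg.inv(fit.covariance)
    u = resid.T @ gc  # (p,)
    Iinv_u = fit.covariance @ u
    # per-term: based on the k-th scaled residual alone
    diag_inv = np.diag(fit.covariance)
    term_stats = d * Iinv_u**2 / (diag_inv * sum_g2)
    term_p = stats.chi2.sf(term_stats, 1)
    global_stat = float(d * (u @ Iinv_u) / sum_g2)
    p = len(fit.terms)
    global_p = float(stats.chi2.sf(global_stat, p))
    # descriptive correlation of g with each scaled residual column
    scaled = d * (resid @ fit.covariance) + fit.beta[None, :]
    corr = np.array(
        [
            np.corrcoef(g, scaled[:, k])[0, 1] if np.std(scaled[:, k]) > 0 else 0.0
            for k in range(p)
        ]
    )
    return PhDiagnostics(
        terms=list(fit.terms),
        correlations=corr,
        term_statistics=np.asarray(term_stats, dtype=float),
        term_p_values=np.asarray(term_p, dtype=float),
        global_statistic=global_stat,
        global_df=p,
        global_p_value=global_p,
    )
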
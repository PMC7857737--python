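"""Recursive-partitioning survival trees with maximally selected log-rank splits.

Each node searches its covariates for the binary split maximising the
two-group log-rank statistic — over midpoints between consecutive distinct
values for continuous variables, over order-respecting cuts for ordinal ones
(the CNA quartile), and over binary level partitions for nominal ones — and
splits when the Bonferroni-adjusted p-value (adjusted over the number of
candidate splits actually evaluated) is below alpha.  Both children must keep
at least ``min_node`` subjects.  Leaves carry Kaplan-Meier curves.

This is a deterministic stand-in for conditional-inference survival trees:
the split statistic is the same, the multiplicity adjustment is Bonferroni
rather than a permutation distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import survkit

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_NODE = 20
MAX_NOMINAL_LEVELS = 10


@dataclass
class SplitResult:
    """Best binary split of one variable at one node."""

    variable: str
    kind: str  # "continuous" | "ordinal" | "nominal"
    cut: float | None  # midpoint threshold (continuous / ordinal)
    left_levels: tuple | None  # level subset going left (categorical)
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    n_candidates: int


def _logrank_scan_matrices(times, events):
    """Per-event-time at-risk/death indicator rows for the scan formula."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    ev_times = np.unique(t[e == 1])
    A = t[None, :] >= ev_times[:, None]  # (m, n) at-risk indicators
    D = (t[None, :] == ev_times[:, None]) & (e[None, :] == 1)
    n_j = A.sum(axis=1).astype(float)
    d_j = D.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_j = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1.0), 0.0)
    return A.astype(float), D.astype(float), n_j, d_j, c_j


def _two_group_stats(n1, d1, n_j, d_j, c_j):
    """Log-rank chi-square for group-1 at-risk/death count columns.

    ``n1``/``d1`` have shape (m,) or (m, k) for k candidate groupings.
    """
    frac = n1 / n_j[..., None] if n1.ndim == 2 else n1 / n_j
    if n1.ndim == 2:
        U = (d1 - d_j[:, None] * frac).sum(axis=0)
        V = (c_j[:, None] * frac * (1.0 - frac)).sum(axis=0)
    else:
        U = (d1 - d_j * frac).sum()
        V = (c_j * frac * (1.0 - frac)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(V > 0, U**2 / V, 0.0)
    return stat


def best_split(
    times,
    events,
    values,
    kind: str = "continuous",
    levels=None,
    min_node: int = DEFAULT_MIN_NODE,
) -> SplitResult | None:
    """Best binary split of one variable by maximally selected log-rank.

    Returns None when no candidate leaves ``min_node`` subjects on both
    sides (or the variable is constant).  The adjusted p-value is the
    unadjusted chi-square p times the number of candidates evaluated.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size < 2 * min_node or e.sum() == 0:
        return None
    A, D, n_j, d_j, c_j = _logrank_scan_matrices(t, e)

    if kind in ("continuous", "ordinal"):
        x = np.asarray(values, dtype=float)
        order = np.argsort(x, kind="stable")
        xs = x[order]
        # candidate boundaries: between consecutive distinct values,
        # both sides >= min_node
        boundaries = np.nonzero(np.diff(xs) > 0)[0] + 1  # left side size k
        boundaries = boundaries[(boundaries >= min_node) & (t.size - boundaries >= min_node)]
        if boundaries.size == 0:
            return None
        n1_cum = np.cumsum(A[:, order], axis=1)
        d1_cum = np.cumsum(D[:, order], axis=1)
        n1 = n1_cum[:, boundaries - 1]
        d1 = d1_cum[:, boundaries - 1]
        stat = _two_group_stats(n1, d1, n_j, d_j, c_j)
        best = int(np.argmax(stat))
        k = boundaries[best]
        cut = float((xs[k - 1] + xs[k]) / 2.0)
        best_stat = float(stat[best])
        n_cand = int(boundaries.size)
        p_un = float(stats.chi2.sf(best_stat, 1))
        return SplitResult(
            variable="",
            kind=kind,
            cut=cut,
            left_levels=None,
            statistic=best_stat,
            p_unadjusted=p_un,
            p_adjusted=min(1.0, p_un * n_cand),
            n_candidates=n_cand,
        )

    if kind == "nominal":
        vals = pd.Series(values).astype(str).to_numpy()
        obs_levels = [l for l in (levels or pd.unique(vals)) if (vals == l).any()]
        L = len(obs_levels)
        if L < 2:
            return None
        if L > MAX_NOMINAL_LEVELS:
            raise ValueError(
                f"nominal variable has {L} levels (> {MAX_NOMINAL_LEVELS}): "
                "too many binary partitions"
            )
        # per-level at-risk / death count rows
        memb = np.array([(vals == l) for l in obs_levels], dtype=float)  # (L, n)
        n_lv = A @ memb.T  # (m, L)
        d_lv = D @ memb.T
        sizes = memb.sum(axis=1)
        best_res = None
        n_cand = 0
        # non-empty proper subsets containing the first level (avoid mirror dupes)
        rest = list(range(1, L))
        for r in range(0, L - 1):
            for combo in combinations(rest, r):
                subset = (0,) + combo
                size_left = sizes[list(subset)].sum()
                if size_left < min_node or (t.size - size_left) < min_node:
                    continue
                n_cand += 1
                n1 = n_lv[:, list(subset)].sum(axis=1)
                d1 = d_lv[:, list(subset)].sum(axis=1)
                s = float(_two_group_stats(n1, d1, n_j, d_j, c_j))
                if best_res is None or s > best_res[0]:
                    best_res = (s, subset)
        if best_res is None:
            return None
        s, subset = best_res
        p_un = float(stats.chi2.sf(s, 1))
        return SplitResult(
            variable="",
            kind="nominal",
            cut=None,
            left_levels=tuple(obs_levels[i] for i in subset),
            statistic=s,
            p_unadjusted=p_un,
            p_adjusted=min(1.0, p_un * n_cand),
            n_candidates=n_cand,
        )

    raise ValueError(f"unknown variable kind: {kind!r}")


@dataclass
class TreeNode:
    id: int
    depth: int
    n: int
    patient_ids: list
    split: SplitResult | None = None
    children: tuple | None = None  # (left_id, right_id)
    km: survkit.SurvivalCurve | None = None
    median: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SurvTree:
    """Binary survival tree; node 0 is the root."""

    nodes: dict = field(default_factory=dict)
    outcome: str = "DSS"
    alpha: float = DEFAULT_ALPHA
    min_node: int = DEFAULT_MIN_NODE

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def leaves(self) -> list[TreeNode]:
        return [nd for nd in self.nodes.values() if nd.is_leaf]

    @property
    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes.values())

    def to_dict(self) -> dict:
        out = {"outcome": self.outcome, "alpha": self.alpha, "min_node": self.min_node, "nodes": []}
        for nd in self.nodes.values():
            entry = {
                "id": nd.id,
                "depth": nd.depth,
                "n": nd.n,
                "is_leaf": nd.is_leaf,
                "median_survival": nd.median,
            }
            if nd.split is not None:
                entry["split"] = {
                    "variable": nd.split.variable,
                    "kind": nd.split.kind,
                    "cut": nd.split.cut,
                    "left_levels": list(nd.split.left_levels) if nd.split.left_levels else None,
                    "statistic": nd.split.statistic,
                    "p_adjusted": nd.split.p_adjusted,
                    "children": list(nd.children),
                }
            out["nodes"].append(entry)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def render(self) -> str:
        if self.root.is_leaf:
            return (
                f"root only — no significant partition "
                f"(n={self.root.n}, alpha={self.alpha})"
            )
        lines: list[str] = []

        def walk(node_id: int, prefix: str, label: str) -> None:
            nd = self.nodes[node_id]
            med = "not reached" if nd.median is None else f"{nd.median:.1f}"
            if nd.is_leaf:
                lines.append(f"{prefix}{label}leaf [{nd.id}] n={nd.n} median={med}")
                return
            sp = nd.split
            if sp.left_levels is not None:
                desc = f"{sp.variable} in {{{', '.join(sp.left_levels)}}}"
            else:
                desc = f"{sp.variable} <= {sp.cut:g}"
            lines.append(
                f"{prefix}{label}[{nd.id}] n={nd.n} split: {desc} "
                f"(p_adj={sp.p_adjusted:.4g})"
            )
            walk(nd.children[0], prefix + "  ", "yes: ")
            walk(nd.children[1], prefix + "  ", "no:  ")

        walk(0, "", "")
        return "\n".join(lines)


def _variable_kind(series: pd.Series) -> str:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return "ordinal" if series.cat.ordered else "nominal"
    if series.dtype == object:
        return "nominal"
    return "continuous"


def fit_survival_tree(
    clinical,
    score=None,
    predictors: list[str] | None = None,
    outcome: str = "DSS",
    alpha: float = DEFAULT_ALPHA,
    min_node: int = DEFAULT_MIN_NODE,
) -> SurvTree:
    """Grow a survival tree by recursive maximally-selected log-rank splits.

    ``predictors`` may name clinical columns, ``cna_score`` or ``quartile``
    (the latter two looked up in ``score``).  Splitting stops when the best
    Bonferroni-adjusted p at a node is >= alpha or the node is too small.
    """
    if not predictors:
        raise ValueError("predictors list is empty")
    frame = clinical.data
    if score is not None:
        shared = frame.index.intersection(score.table.index)
        frame = frame.loc[shared].join(score.table.loc[shared])
    missing = [v for v in predictors if v not in frame.columns]
    if missing:
        raise ValueError(f"unknown predictors: {missing}")
    t_all = frame[f"{outcome.lower()}_months"].to_numpy(dtype=float)
    e_all = frame[f"{outcome.lower()}_event"].to_numpy(dtype=int)

    tree = SurvTree(outcome=outcome.upper(), alpha=alpha, min_node=min_node)
    next_id = [0]

    def grow(index: pd.Index, depth: int) -> int:
        node_id = next_id[0]
        next_id[0] += 1
        pos = frame.index.get_indexer(index)
        t, e = t_all[pos], e_all[pos]
        node = TreeNode(node_id, depth, n=len(index), patient_ids=list(index))
        tree.nodes[node_id] = node
        best: SplitResult | None = None
        if len(index) >= 2 * min_node and e.sum() > 0:
            for var in predictors:
                s = frame.loc[index, var]
                mask = s.notna().to_numpy()
                if mask.sum() < len(index):
                    # keep the partition exact: skip variables with missing
                    # values at this node rather than dropping patients
                    continue
                kind = _variable_kind(s)
                if kind == "ordinal":
                    vals = s.cat.codes.to_numpy(dtype=float)
                    res = best_split(t, e, vals, kind="ordinal", min_node=min_node)
                    if res is not None:
                        # report the ordinal cut as the level subset
                        left = tuple(
                            str(l)
                            for i, l in enumerate(s.cat.categories)
                            if i <= res.cut
                        )
                        res.left_levels = left
                elif kind == "nominal":
                    lv = sorted(s.astype(str).unique())
                    res = best_split(t, e, s, kind="nominal", levels=lv, min_node=min_node)
                else:
                    res = best_split(
                        t, e, s.to_numpy(dtype=float), kind="continuous", min_node=min_node
                    )
                if res is None:
                    continue
                res.variable = var
                if (
                    best is None
                    or res.p_adjusted < best.p_adjusted
                    or (res.p_adjusted == best.p_adjusted and res.statistic > best.statistic)
                ):
                    best = res
        if best is not None and best.p_adjusted < alpha:
            s = frame.loc[index, best.variable]
            if best.kind == "continuous":
                go_left = s.to_numpy(dtype=float) <= best.cut
            elif best.kind == "ordinal":
                go_left = s.cat.codes.to_numpy(dtype=float) <= best.cut
            else:
                go_left = s.astype(str).isin(best.left_levels).to_numpy()
            left_idx, right_idx = index[go_left], index[~go_left]
            node.split = best
            lid = grow(left_idx, depth + 1)
            rid = grow(right_idx, depth + 1)
            node.children = (lid, rid)
        else:
            node.km = survkit.km_estimate(t, e)
            node.median = survkit.median_survival(node.km)
        return node_id

    grow(frame.index, 0)
    # exact-partition invariant
    leaf_total = sum(nd.n for nd in tree.leaves)
    assert leaf_total == len(frame), "tree leaves do not partition the cohort"
    return tree


def fit_survival_tree_quartile(
    clinical,
    score,
    extra_predictors: list[str] | None = None,
    outcome: str = "DSS",
    alpha: float = DEFAULT_ALPHA,
    min_node: int = DEFAULT_MIN_NODE,
) -> SurvTree:
    """Survival tree on the ordinal CNA quartile (plus optional covariates).

    Candidate quartile splits respect the order: Q1|Q234, Q12|Q34, Q123|Q4.
    """
    predictors = ["quartile"] + list(extra_predictors or [])
    return fit_survival_tree(
        clinical,
        score,
        predictors=predictors,
        outcome=outcome,
        alpha=alpha,
        min_node=min_node,
    )
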
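"""Connectome-based predictive modeling (CPM) of behavior.

The CPM recipe, per cross-validation fold:

1. normalize the behavioral score and every edge with the *training* mean and
   standard deviation (test data reuse the training normalizers);
2. feature selection by partial Spearman correlation between behavior and each
   edge, controlling nuisance covariates (age, sex, education, head motion by
   default); edges with two-tailed ``p < alpha`` are split by correlation sign
   into a positive and a negative network;
3. network strength = sum of the selected (normalized) edges per subject;
4. one ordinary least-squares line per tail mapping strength to normalized
   behavior, applied to the held-out subject(s).

Leave-one-out cross-validation (LOOCV) is the primary scheme, suited to the
n < 200 sample the model targets; repeated k-fold is provided as a control.
The partial Spearman screen is computed as rank-transform -> residualize on
ranked covariates -> Pearson on the residuals, with p-values from the
t-distribution on ``n - 2 - c`` degrees of freedom.

Implementation notes: edges are ranked within each training subset exactly
(average ranks for ties) using a drop-subjects update of the full-sample
ranks, and the per-edge screen is evaluated with dense linear algebra, so a
full LOOCV over ~10k edges and ~100 subjects runs in well under a second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_connectome import SubjectConnectome, stack_edges

logger = logging.getLogger("trustcpm")

DEFAULT_COVARIATES = ("age", "sex", "education", "fd")


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class CpmConfig:
    """Tunable parameters of the CPM pipeline.

    selection_alpha
        Two-tailed p threshold of the edge screen (default .01).
    cv_scheme
        ``"loocv"`` or ``"kfold"``.
    k, repeats
        Folds and repetitions of the k-fold scheme (defaults 10 and 100).
    permutations
        Default permutation count for significance testing (5000).
    small_sample_p_rule
        ``"ratio"`` (count/B, the plain definition) or ``"add_one"``
        ((count+1)/(B+1), which avoids exact zeros).
    """

    selection_alpha: float = 0.01
    cv_scheme: str = "loocv"
    k: int = 10
    repeats: int = 100
    permutations: int = 5000
    seed: int = 0
    small_sample_p_rule: str = "ratio"
    target: str = "trust"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if not 0.0 < self.selection_alpha < 1.0:
            raise ValueError("selection_alpha must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.cv_scheme not in ("loocv", "kfold"):
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")
        if self.small_sample_p_rule not in ("ratio", "add_one"):
            raise ValueError("small_sample_p_rule must be 'ratio' or 'add_one'")


@dataclass
class FoldModel:
    """Everything learned from one training fold."""

    test_subjects: np.ndarray
    positive_edges: np.ndarray
    negative_edges: np.ndarray
    behavior_normalizer: tuple[float, float]  # (mean, sd) of training behavior
    positive_model: tuple[float, float]  # (intercept, slope)
    negative_model: tuple[float, float]
    edge_normalizers: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)


@dataclass
class CpmResult:
    """Aggregated cross-validated predictions (normalized units)."""

    subject_ids: list[str]
    actual: np.ndarray  # raw behavior
    actual_z: np.ndarray  # behavior normalized with each subject's own-fold training params
    predicted_pos: np.ndarray
    predicted_neg: np.ndarray
    folds: list[FoldModel]
    cv_scheme: str
    config: CpmConfig

    def assessment(self) -> dict[str, "Assessment"]:
        """Spearman r and MSE for the positive and the negative model."""
        from .statistical_inference import assess

        return {
            "positive": assess(self.predicted_pos, self.actual, self.actual_z),
            "negative": assess(self.predicted_neg, self.actual, self.actual_z),
        }


@dataclass
class KfoldResult:
    """Repeated k-fold CPM: per-repeat performance and its spread."""

    results: list[CpmResult]
    r_pos: np.ndarray
    mse_pos: np.ndarray
    r_neg: np.ndarray
    mse_neg: np.ndarray

    def summary(self) -> dict[str, float]:
        return {
            "r_pos_mean": float(self.r_pos.mean()),
            "r_pos_std": float(self.r_pos.std(ddof=1)) if self.r_pos.size > 1 else 0.0,
            "mse_pos_mean": float(self.mse_pos.mean()),
            "r_neg_mean": float(self.r_neg.mean()),
            "r_neg_std": float(self.r_neg.std(ddof=1)) if self.r_neg.size > 1 else 0.0,
            "mse_neg_mean": float(self.mse_neg.mean()),
        }


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_fit_apply(
    train_values: np.ndarray, test_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Z-score train and test with the *training* mean and SD (ddof=1).

    Returns ``(train_z, test_z, (mean, sd))``; raises on a constant training
    vector (zero SD), which cannot be normalized.
    """
    train_values = np.asarray(train_values, dtype=float)
    test_values = np.asarray(test_values, dtype=float)
    mean = float(train_values.mean())
    sd = float(train_values.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot normalize a constant training feature")
    return (train_values - mean) / sd, (test_values - mean) / sd, (mean, sd)


# ---------------------------------------------------------------------------
# Ranking utilities
# ---------------------------------------------------------------------------

def _rank_columns(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks per column, plus a mask of columns containing ties.

    Tie-free columns are ranked with two argsorts; the (typically few) tied
    columns are re-ranked exactly with average ranks.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    order = np.argsort(a, axis=0, kind="stable")
    ranks = np.empty_like(a)
    np.put_along_axis(ranks, order, np.arange(1.0, n + 1.0)[:, None], axis=0)
    sorted_vals = np.take_along_axis(a, order, axis=0)
    tied_cols = (sorted_vals[1:] == sorted_vals[:-1]).any(axis=0)
    for c in np.flatnonzero(tied_cols):
        ranks[:, c] = stats.rankdata(a[:, c])
    return ranks, tied_cols


def _rank_columns_discrete(a: np.ndarray) -> np.ndarray:
    """Average ranks per column for data over a small set of distinct values.

    Counting-based: per column, rank of a value class = (# smaller values)
    + (class count + 1) / 2.  Falls back to :func:`_rank_columns` when the
    value set is large.
    """
    vals = np.unique(a)
    if vals.size > 64:
        return _rank_columns(a)[0]
    nt, B = a.shape
    idx = np.searchsorted(vals, a)
    flat = idx * B + np.arange(B)[None, :]
    counts = np.bincount(flat.ravel(), minlength=vals.size * B).reshape(vals.size, B)
    less = np.cumsum(counts, axis=0) - counts
    rankmap = less + (counts + 1) / 2.0
    return rankmap[idx, np.arange(B)[None, :]]


def _subset_ranks(
    E: np.ndarray,
    R_full: np.ndarray,
    train: np.ndarray,
    dropped: np.ndarray,
    tied_cols: np.ndarray,
) -> np.ndarray:
    """Exact average ranks of ``E[train]`` columns via a drop-rows update.

    Dropping a set D of rows changes the average rank of value v by
    ``sum_{d in D} (1[v > v_d] + 0.5 * 1[v == v_d])``, which holds with
    average-rank ties.  Both indicators are evaluated on the full-sample
    ranks themselves (average ranks order exactly as the values do), and the
    equality term only on columns that contain ties.
    """
    R = R_full[train]  # fancy indexing copies; safe to update in place
    tc = np.flatnonzero(tied_cols) if tied_cols.any() else None
    if len(dropped) == 1:
        row = R_full[dropped[0]]
        eq = (R[:, tc] == row[tc]) if tc is not None else None
        np.subtract(R, R > row, out=R, casting="unsafe")
        if tc is not None:
            R[:, tc] -= 0.5 * eq
        return R
    adjust = np.zeros_like(R)
    for d in dropped:
        row = R_full[d]
        np.add(adjust, R > row, out=adjust, casting="unsafe")
        if tc is not None:
            adjust[:, tc] += 0.5 * (R[:, tc] == row[tc])
    R -= adjust
    return R


def _rank_sumsq(nt: int) -> float:
    """Sum of squared ranks 1..nt (column sum of squares without ties)."""
    return nt * (nt + 1) * (2 * nt + 1) / 6.0


# ---------------------------------------------------------------------------
# Partial Spearman correlation
# ---------------------------------------------------------------------------

def _ranked_partial_corr(
    ry: np.ndarray, Z: np.ndarray, R: np.ndarray, css0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Partial correlation of ranked behavior with each ranked-edge column.

    ``ry`` and the columns of ``R`` are ranks; ``Z`` is the design matrix of
    ranked covariates including an intercept column.  Both sides are
    residualized on ``Z`` and correlated.  ``css0`` may supply the column
    sums of squares of ``R`` when the caller knows them.  Returns
    ``(rho, valid)`` where ``valid`` flags columns with non-degenerate
    residual variance.
    """
    G = Z.T @ Z
    try:
        coef_y = np.linalg.solve(G, Z.T @ ry)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient covariate design") from exc
    u = ry - Z @ coef_y
    uu = float(u @ u)
    H = Z.T @ R
    B = np.linalg.solve(G, H)
    if css0 is None:
        css0 = np.einsum("ij,ij->j", R, R)
    css = css0 - np.einsum("ij,ij->j", H, B)
    num = u @ R
    valid = css > 1e-10 * np.maximum(css0, 1.0)
    rho = np.zeros(R.shape[1])
    if uu > 1e-12 * max(float(ry @ ry), 1.0):
        denom = np.sqrt(uu * css[valid])
        rho[valid] = num[valid] / denom
        np.clip(rho, -1.0, 1.0, out=rho)
    else:
        valid = np.zeros_like(valid)
    return rho, valid


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    Ranks all variables (average ranks for ties), residualizes the ranked
    ``x`` and ``y`` on the ranked covariates (plus intercept) by least
    squares, and returns the Pearson correlation of the residuals with a
    two-tailed p-value from the t-distribution on ``n - 2 - c`` degrees of
    freedom.  Degenerate inputs (constant variable, or residuals that vanish
    because a covariate duplicates the variable) return ``(0.0, 1.0)`` and
    are thereby never selectable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or np.size(covariates) == 0:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates must be an n x c array")
    c = C.shape[1]
    if n < c + 4:
        raise ValueError(f"need at least c + 4 = {c + 4} observations, got {n}")
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(C[:, j]) for j in range(c)])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient covariate design")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_vec, valid = _ranked_partial_corr(ry, Z, rx[:, None])
    if not valid[0]:
        return 0.0, 1.0
    rho = float(rho_vec[0])
    df = n - 2 - c
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def _selection_threshold(alpha: float, df: int) -> float:
    """|rho| above which the two-tailed t-approximation p falls below alpha."""
    t_crit = stats.t.isf(alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit * t_crit))


@dataclass
class EdgeSelection:
    positive: np.ndarray
    negative: np.ndarray
    rho: np.ndarray
    p: np.ndarray


def select_edges(
    edges: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.01,
) -> EdgeSelection:
    """Screen every edge by partial Spearman correlation with behavior.

    ``edges`` is an ``n_subjects x n_edges`` matrix of canonical edge
    vectors.  Edges with two-tailed ``p < alpha`` are split by sign of the
    partial correlation into the positive and negative sets (disjoint by
    construction).
    """
    E = np.asarray(edges, dtype=float)
    y = np.asarray(behavior, dtype=float)
    n = E.shape[0]
    if y.size != n:
        raise ValueError("behavior length does not match edge matrix")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float).reshape(n, -1)
    c = C.shape[1]
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(C[:, j]) for j in range(c)])
    ry = stats.rankdata(y)
    R, _ = _rank_columns(E)
    rho, valid = _ranked_partial_corr(ry, Z, R)
    df = n - 2 - c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / np.maximum(1.0 - rho * rho, 1e-300))
    p = np.where(valid, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    r_crit = _selection_threshold(alpha, df)
    positive = np.flatnonzero(valid & (rho > r_crit))
    negative = np.flatnonzero(valid & (rho < -r_crit))
    return EdgeSelection(positive=positive, negative=negative, rho=rho, p=p)


# ---------------------------------------------------------------------------
# Strengths and linear models
# ---------------------------------------------------------------------------

def network_strength(edge_vector: np.ndarray, selected: np.ndarray) -> float:
    """Sum of the edge values at the selected indices (0 for an empty set)."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        return 0.0
    if selected.min() < 0 or selected.max() >= edge_vector.size:
        raise IndexError("selected edge index out of range")
    return float(edge_vector[selected].sum())


def fit_strength_model(
    strengths: np.ndarray, behavior_normalized: np.ndarray
) -> tuple[float, float]:
    """OLS line ``behavior = intercept + slope * strength``.

    Constant strengths (including the empty-selection case where every
    strength is 0) fall back to an intercept-only model predicting the
    training mean; the caller logs that event.
    """
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(behavior_normalized, dtype=float)
    if s.size != y.size or s.size < 3:
        raise ValueError("need >= 3 matched (strength, behavior) points")
    sm = s.mean()
    var = float(((s - sm) ** 2).sum())
    if var == 0.0:
        return float(y.mean()), 0.0
    slope = float(((s - sm) * (y - y.mean())).sum() / var)
    intercept = float(y.mean() - slope * sm)
    return intercept, slope


# ---------------------------------------------------------------------------
# Cross-validation machinery
# ---------------------------------------------------------------------------

class _EdgeWorkspace:
    """Per-dataset precomputation shared across folds (and permutations)."""

    def __init__(self, E: np.ndarray):
        self.E = np.ascontiguousarray(E, dtype=float)
        self.R_full, self.tied_cols = _rank_columns(self.E)
        self.n, self.m = self.E.shape
        self.colsum = self.E.sum(axis=0)
        self.colsumsq = np.einsum("ij,ij->j", self.E, self.E)

    def subset_columns(self, mask: np.ndarray) -> "_EdgeWorkspace":
        """Workspace restricted to an edge subset (column ranks are intact)."""
        ws = object.__new__(_EdgeWorkspace)
        ws.E = np.ascontiguousarray(self.E[:, mask])
        ws.R_full = np.ascontiguousarray(self.R_full[:, mask])
        ws.tied_cols = self.tied_cols[mask]
        ws.n, ws.m = ws.E.shape
        ws.colsum = self.colsum[mask]
        ws.colsumsq = self.colsumsq[mask]
        return ws

    def fold_rank_sumsq(self, R_tr: np.ndarray) -> np.ndarray:
        """Column sums of squares of training edge ranks.

        Closed form for tie-free columns (ranks are a permutation of
        ``1..n_train``); tied columns are summed explicitly.
        """
        nt = R_tr.shape[0]
        css0 = np.full(self.m, _rank_sumsq(nt))
        if self.tied_cols.any():
            tc = np.flatnonzero(self.tied_cols)
            css0[tc] = np.einsum("ij,ij->j", R_tr[:, tc], R_tr[:, tc])
        return css0

    def fold_edge_moments(self, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge training mean and SD (ddof=1) via drop-rows correction."""
        nt = self.n - len(test)
        Ete = self.E[test]
        s1 = self.colsum - Ete.sum(axis=0)
        s2 = self.colsumsq - np.einsum("ij,ij->j", Ete, Ete)
        mu = s1 / nt
        var = np.maximum(s2 - nt * mu * mu, 0.0) / (nt - 1)
        return mu, np.sqrt(var)


@dataclass
class CpmData:
    """Edge matrix, behavior and covariates, row-aligned by subject."""

    edges: np.ndarray
    subject_ids: list[str]
    behavior: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...]


def prepare_data(
    connectomes: Sequence[SubjectConnectome] | np.ndarray,
    behavior_table: pd.DataFrame,
    config: CpmConfig,
) -> CpmData:
    """Align connectomes with the behavioral table.

    ``connectomes`` may be a list of :class:`SubjectConnectome` (matched to
    the table by ``subject_id``) or a ready ``n_subjects x n_edges`` edge
    matrix (assumed row-aligned with the table).
    """
    bt = behavior_table.reset_index(drop=True)
    missing = [c for c in (config.target, *config.covariates) if c not in bt.columns]
    if missing:
        raise ValueError(f"behavior table missing column(s): {missing}")
    if isinstance(connectomes, np.ndarray):
        E = np.asarray(connectomes, dtype=float)
        if E.shape[0] != len(bt):
            raise ValueError("edge matrix and behavior table disagree on n subjects")
        ids = (
            [str(s) for s in bt["subject_id"]]
            if "subject_id" in bt.columns
            else [str(i) for i in range(len(bt))]
        )
    else:
        E, conn_ids = stack_edges(connectomes)
        if "subject_id" not in bt.columns:
            raise ValueError("behavior table needs a subject_id column")
        table_ids = [str(s) for s in bt["subject_id"]]
        if set(conn_ids) != set(table_ids):
            raise ValueError("subject ids of connectomes and behavior table differ")
        bt = bt.set_index("subject_id").loc[conn_ids].reset_index()
        ids = conn_ids
    y = bt[config.target].to_numpy(dtype=float)
    C = bt[list(config.covariates)].to_numpy(dtype=float) if config.covariates else np.empty((len(bt), 0))
    if not np.isfinite(y).all() or not np.isfinite(C).all():
        raise ValueError("non-finite behavior or covariate values")
    return CpmData(edges=E, subject_ids=ids, behavior=y, covariates=C,
                   covariate_names=tuple(config.covariates))


def aligned_behavior_table(data: CpmData, config: CpmConfig) -> pd.DataFrame:
    """Rebuild a behavior table row-aligned with ``data.edges``."""
    bt = pd.DataFrame({"subject_id": data.subject_ids,
                       config.target: data.behavior})
    for j, name in enumerate(data.covariate_names):
        bt[name] = data.covariates[:, j]
    return bt


def _covariate_design(C_train: np.ndarray) -> np.ndarray:
    n = C_train.shape[0]
    cols = [np.ones(n)]
    cols += [stats.rankdata(C_train[:, j]) for j in range(C_train.shape[1])]
    return np.column_stack(cols)


def _fit_fold(
    ws: _EdgeWorkspace,
    y: np.ndarray,
    C: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    config: CpmConfig,
) -> tuple[FoldModel, np.ndarray, np.ndarray, np.ndarray]:
    """Train on ``train``, predict ``test``.

    Returns the fold model plus (pred_pos, pred_neg, actual_z) for the test
    subjects, all in the training normalization's z units.
    """
    y_tr = y[train]
    mu_y = float(y_tr.mean())
    sd_y = float(y_tr.std(ddof=1))
    if sd_y == 0.0:
        raise ValueError("behavior constant within a training fold")
    y_tr_z = (y_tr - mu_y) / sd_y

    Z = _covariate_design(C[train])
    ry = stats.rankdata(y_tr)
    R_tr = _subset_ranks(ws.E, ws.R_full, train, test, ws.tied_cols)
    rho, valid = _ranked_partial_corr(ry, Z, R_tr, ws.fold_rank_sumsq(R_tr))
    df = len(train) - 2 - C.shape[1]
    r_crit = _selection_threshold(config.selection_alpha, df)
    pos = np.flatnonzero(valid & (rho > r_crit))
    neg = np.flatnonzero(valid & (rho < -r_crit))

    mu_e, sd_e = ws.fold_edge_moments(test)

    models: dict[str, tuple[float, float]] = {}
    normalizers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    preds: dict[str, np.ndarray] = {}
    for tail, sel in (("positive", pos), ("negative", neg)):
        if sel.size == 0:
            models[tail] = (0.0, 0.0)  # training mean in z units is 0
            normalizers[tail] = (np.empty(0), np.empty(0))
            preds[tail] = np.zeros(len(test))
            continue
        mu_s, sd_s = mu_e[sel], sd_e[sel]
        s_tr = ((ws.E[np.ix_(train, sel)] - mu_s) / sd_s).sum(axis=1)
        intercept, slope = fit_strength_model(s_tr, y_tr_z)
        s_te = ((ws.E[np.ix_(test, sel)] - mu_s) / sd_s).sum(axis=1)
        models[tail] = (intercept, slope)
        normalizers[tail] = (mu_s, sd_s)
        preds[tail] = intercept + slope * s_te

    fold = FoldModel(
        test_subjects=np.asarray(test),
        positive_edges=pos,
        negative_edges=neg,
        behavior_normalizer=(mu_y, sd_y),
        positive_model=models["positive"],
        negative_model=models["negative"],
        edge_normalizers=normalizers,
    )
    actual_z = (y[test] - mu_y) / sd_y
    return fold, preds["positive"], preds["negative"], actual_z


def _run_cv(
    ws: _EdgeWorkspace,
    y: np.ndarray,
    C: np.ndarray,
    folds: list[np.ndarray],
    subject_ids: list[str],
    config: CpmConfig,
    scheme_name: str,
) -> CpmResult:
    n = ws.n
    pred_pos = np.full(n, np.nan)
    pred_neg = np.full(n, np.nan)
    actual_z = np.full(n, np.nan)
    fold_models: list[FoldModel] = []
    all_idx = np.arange(n)
    n_empty = {"positive": 0, "negative": 0}
    for test in folds:
        test = np.sort(np.asarray(test, dtype=int))
        train = np.setdiff1d(all_idx, test)
        fold, pp, pn, az = _fit_fold(ws, y, C, train, test, config)
        pred_pos[test] = pp
        pred_neg[test] = pn
        actual_z[test] = az
        fold_models.append(fold)
        if fold.positive_edges.size == 0:
            n_empty["positive"] += 1
        if fold.negative_edges.size == 0:
            n_empty["negative"] += 1
    for tail, k in n_empty.items():
        if k:
            logger.warning(
                "%s: %d/%d folds selected no %s edges; those folds predict the "
                "training mean", scheme_name, k, len(folds), tail,
            )
    return CpmResult(
        subject_ids=list(subject_ids),
        actual=y.copy(),
        actual_z=actual_z,
        predicted_pos=pred_pos,
        predicted_neg=pred_neg,
        folds=fold_models,
        cv_scheme=scheme_name,
        config=config,
    )


def run_loocv(
    connectomes: Sequence[SubjectConnectome] | np.ndarray,
    behavior_table: pd.DataFrame,
    config: CpmConfig | None = None,
) -> CpmResult:
    """Leave-one-out cross-validated CPM; each subject is held out once."""
    config = config or CpmConfig()
    data = prepare_data(connectomes, behavior_table, config)
    n = data.edges.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 subjects for LOOCV, got {n}")
    ws = _EdgeWorkspace(data.edges)
    folds = [np.array([i]) for i in range(n)]
    return _run_cv(ws, data.behavior, data.covariates, folds,
                   data.subject_ids, config, "loocv")


def kfold_partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """A random partition of ``range(n)`` into ``k`` near-equal folds."""
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of subjects ({n})")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def run_kfold(
    connectomes: Sequence[SubjectConnectome] | np.ndarray,
    behavior_table: pd.DataFrame,
    config: CpmConfig | None = None,
) -> KfoldResult:
    """Repeated k-fold CPM (the overfitting control for LOOCV).

    Each repeat draws a fresh seeded partition, runs the identical per-fold
    procedure, and is assessed like a LOOCV run; the summary reports the mean
    and SD of r and MSE across repeats.  With ``k == n`` a repeat reduces
    exactly to LOOCV.
    """
    config = config or CpmConfig()
    data = prepare_data(connectomes, behavior_table, config)
    n = data.edges.shape[0]
    ws = _EdgeWorkspace(data.edges)
    rng = np.random.default_rng(config.seed)
    results = []
    for rep in range(config.repeats):
        folds = kfold_partition(n, config.k, rng)
        res = _run_cv(ws, data.behavior, data.covariates, folds,
                      data.subject_ids, config, "kfold")
        results.append(res)
    r_pos, mse_pos, r_neg, mse_neg = [], [], [], []
    for res in results:
        a = res.assessment()
        r_pos.append(a["positive"].r)
        mse_pos.append(a["positive"].mse)
        r_neg.append(a["negative"].r)
        mse_neg.append(a["negative"].mse)
    return KfoldResult(
        results=results,
        r_pos=np.asarray(r_pos),
        mse_pos=np.asarray(mse_pos),
        r_neg=np.asarray(r_neg),
        mse_neg=np.asarray(mse_neg),
    )
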
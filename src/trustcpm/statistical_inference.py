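"""Model assessment, permutation inference, lesion comparison, FDR.

A cross-validated CPM is assessed by the Spearman correlation ``r`` between
predicted and actual behavior plus the mean squared error in normalized
units.  Significance comes from a permutation test that shuffles the
brain-behavior mapping (subject labels of the behavioral rows) and reruns
the entire cross-validation; the p-value of ``r`` is the fraction of
permuted runs with a larger ``r``, and the p-value of MSE the fraction with
a smaller MSE.  Network contributions are probed by computational lesioning:
remove a network, rerun the whole pipeline, and compare the lesioned model's
``r`` against the whole-brain model with a one-tailed Steiger z test for
dependent overlapping correlations, FDR-corrected across networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas_connectome import Atlas, SubjectConnectome, lesion_edge_mask

logger = logging.getLogger("trustcpm")


# ---------------------------------------------------------------------------
# Assessment
# ---------------------------------------------------------------------------

@dataclass
class Assessment:
    """Spearman r and MSE of a prediction; ``r_defined`` is False when the
    predicted vector was constant (r is then reported as 0)."""

    r: float
    mse: float
    r_defined: bool = True


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return 0.0, False
    r = stats.spearmanr(a, b).statistic
    if np.isnan(r):
        return 0.0, False
    return float(r), True


def assess(
    predicted: np.ndarray,
    actual: np.ndarray,
    actual_for_mse: np.ndarray | None = None,
) -> Assessment:
    """Spearman r between predicted and actual, plus mean squared error.

    ``actual_for_mse`` lets the caller rank against the raw behavior while
    computing the squared error on its normalized counterpart (the CPM
    convention: predictions live in training z units).  A constant predicted
    vector has no defined rank correlation; it is reported as r = 0 with
    ``r_defined=False``.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size < 3:
        raise ValueError("predicted and actual must be equal-length, n >= 3")
    r, defined = _safe_spearman(predicted, actual)
    ref = actual if actual_for_mse is None else np.asarray(actual_for_mse, dtype=float)
    mse = float(np.mean((predicted - ref) ** 2))
    return Assessment(r=r, mse=mse, r_defined=defined)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Steiger's z for dependent overlapping correlations
# ---------------------------------------------------------------------------

def steiger_compare(
    r_whole: float, r_lesion: float, r_between_predictions: float, n: int
) -> tuple[float, float]:
    """One-tailed Steiger z test of H1: ``r_whole > r_lesion``.

    Both correlations share the actual-behavior variable; their dependence is
    carried by ``r_between_predictions``, the correlation between the two
    prediction vectors.  Uses Fisher-transformed correlations and the
    mean-correlation form of the covariance term:

        c = [r12 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r12^2) / 2] / (1 - rbar^2)^2
        Z = (z1 - z2) sqrt((n - 3) / (2 - 2 c)),   rbar = (r1 + r2) / 2

    with the one-tailed p = P(N(0,1) >= Z).
    """
    if n < 4:
        raise ValueError("need n >= 4 subjects")
    r1, r2, r12 = float(r_whole), float(r_lesion), float(r_between_predictions)
    for name, r in (("r_whole", r1), ("r_lesion", r2), ("r_between", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} = {r} is degenerate (|r| >= 1)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = (r1 + r2) / 2.0
    rbar2 = rbar * rbar
    c = (r12 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r12 * r12)) / (
        (1.0 - rbar2) ** 2
    )
    # near-degenerate triples can push the estimated covariance of the two
    # Fisher z's slightly past 1; clip to keep the variance non-negative
    c = min(c, 1.0 - 1e-12)
    Z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = float(stats.norm.sf(Z))
    return float(Z), p


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Null distributions and p-values of a permuted CPM.

    ``null_r``/``null_mse`` map model tail ("positive"/"negative") to the B
    permuted statistics; ``p_r[t] = #(null_r > r_actual) / B`` and
    ``p_mse[t] = #(null_mse < mse_actual) / B`` (or the add-one variant).
    """

    observed: "object"  # CpmResult
    null_r: dict[str, np.ndarray]
    null_mse: dict[str, np.ndarray]
    p_r: dict[str, float]
    p_mse: dict[str, float]
    n_permutations: int
    scheme: str


def _perm_pvalue(count: int, B: int, rule: str) -> float:
    if rule == "add_one":
        return (count + 1) / (B + 1)
    return count / B


def permutation_test(
    connectomes: "Sequence[SubjectConnectome] | np.ndarray",
    behavior_table: pd.DataFrame,
    config=None,
    *,
    n_permutations: int | None = None,
    scheme: str = "joint",
    observed=None,
    dtype=np.float32,
    tails: tuple[str, ...] = ("positive", "negative"),
) -> PermutationResult:
    """Permutation significance of a LOOCV CPM.

    Each iteration shuffles the subject labels of the behavioral rows against
    the fixed connectomes and reruns the full LOOCV (selection included).
    ``scheme="joint"`` (default) permutes the covariates together with the
    behavior, preserving their coupling; ``scheme="behavior"`` permutes the
    behavioral score alone and leaves the covariates attached to the
    connectomes.  Both schemes target the same brain-behavior null; the
    behavior-only scheme admits a much faster batched evaluation because the
    covariate design is then fixed per fold (its edge-screen inner products
    run in ``dtype``, single precision by default).

    With ``config.cv_scheme == "kfold"`` the statistic is the mean r/MSE of
    the repeated k-fold procedure and each permutation reruns all repeats
    (joint scheme only).  Small B yields coarse p granularity (multiples of
    1/B); a warning is logged below B = 100.
    """
    from .cpm_engine import CpmConfig, _EdgeWorkspace, _run_cv, prepare_data

    config = config or CpmConfig()
    B = int(n_permutations if n_permutations is not None else config.permutations)
    if B < 1:
        raise ValueError("need at least one permutation")
    if B < 100:
        logger.warning("permutation_test: B = %d gives p granularity 1/%d", B, B)
    if scheme not in ("joint", "behavior"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if config.cv_scheme == "kfold":
        if scheme != "joint":
            raise ValueError("k-fold permutation supports the joint scheme only")
        return _permutation_test_kfold(connectomes, behavior_table, config, B,
                                       observed, tails)

    data = prepare_data(connectomes, behavior_table, config)
    ws = _EdgeWorkspace(data.edges)
    n = ws.n
    folds = [np.array([i]) for i in range(n)]
    if observed is None:
        observed = _run_cv(ws, data.behavior, data.covariates, folds,
                           data.subject_ids, config, "loocv")
    obs = observed.assessment()

    rng = np.random.default_rng(config.seed)
    perms = np.array([rng.permutation(n) for _ in range(B)])

    if scheme == "behavior":
        null_r, null_mse = _permute_behavior_loocv(ws, data.behavior, data.covariates,
                                                   perms, config, dtype, tails)
    else:
        null_r = {t: np.empty(B) for t in tails}
        null_mse = {t: np.empty(B) for t in tails}
        for b in range(B):
            pi = perms[b]
            res = _run_cv(ws, data.behavior[pi], data.covariates[pi], folds,
                          data.subject_ids, config, "loocv")
            a = res.assessment()
            for tail in tails:
                null_r[tail][b] = a[tail].r
                null_mse[tail][b] = a[tail].mse

    p_r, p_mse = {}, {}
    for tail in tails:
        p_r[tail] = _perm_pvalue(int((null_r[tail] > obs[tail].r).sum()), B,
                                 config.small_sample_p_rule)
        p_mse[tail] = _perm_pvalue(int((null_mse[tail] < obs[tail].mse).sum()), B,
                                   config.small_sample_p_rule)
    return PermutationResult(
        observed=observed, null_r=null_r, null_mse=null_mse,
        p_r=p_r, p_mse=p_mse, n_permutations=B, scheme=scheme,
    )


def _permutation_test_kfold(connectomes, behavior_table, config, B, observed, tails):
    """Permutation of the repeated k-fold control: the statistic per
    iteration is the mean r and mean MSE across repeats."""
    from .cpm_engine import aligned_behavior_table, prepare_data, run_kfold

    data = prepare_data(connectomes, behavior_table, config)
    aligned = aligned_behavior_table(data, config)
    if observed is None:
        observed = run_kfold(data.edges, aligned, config)
    obs = {"positive": (observed.r_pos.mean(), observed.mse_pos.mean()),
           "negative": (observed.r_neg.mean(), observed.mse_neg.mean())}

    rng = np.random.default_rng(config.seed)
    n = len(aligned)
    null_r = {t: np.empty(B) for t in tails}
    null_mse = {t: np.empty(B) for t in tails}
    for b in range(B):
        pi = rng.permutation(n)
        bt = aligned.copy()
        cols = [config.target, *config.covariates]
        bt[cols] = aligned[cols].to_numpy()[pi]
        kres = run_kfold(data.edges, bt, config)
        stats_by_tail = {"positive": (kres.r_pos.mean(), kres.mse_pos.mean()),
                         "negative": (kres.r_neg.mean(), kres.mse_neg.mean())}
        for t in tails:
            null_r[t][b], null_mse[t][b] = stats_by_tail[t]

    p_r, p_mse = {}, {}
    for t in tails:
        p_r[t] = _perm_pvalue(int((null_r[t] > obs[t][0]).sum()), B,
                              config.small_sample_p_rule)
        p_mse[t] = _perm_pvalue(int((null_mse[t] < obs[t][1]).sum()), B,
                                config.small_sample_p_rule)
    return PermutationResult(observed=observed, null_r=null_r, null_mse=null_mse,
                             p_r=p_r, p_mse=p_mse, n_permutations=B,
                             scheme="joint")


def _permute_behavior_loocv(ws, y, C, perms, config, dtype,
                            tails=("positive", "negative")):
    """Batched LOOCV over behavior-only permutations.

    Fold-invariant quantities (edge ranks within the training set, covariate
    design, edge normalizers, residual variances of the screened edges) are
    computed once per fold and shared by every permutation; the per-edge
    inner products for all permutations are evaluated as one matrix product.
    Produces the same null statistics as rerunning the full LOOCV per
    permutation (up to the precision of ``dtype``).
    """
    from scipy import sparse

    from .cpm_engine import (
        _covariate_design, _rank_columns_discrete, _selection_threshold,
        _subset_ranks,
    )

    n, m = ws.n, ws.m
    B = perms.shape[0]
    Yp = y[perms]  # (B, n): row b is the behavior vector of permutation b
    pred = {t: np.empty((B, n)) for t in tails}
    sqerr = {t: np.zeros(B) for t in tails}
    c = C.shape[1]
    nt = n - 1
    df = nt - 2 - c
    r_crit = _selection_threshold(config.selection_alpha, df)
    all_idx = np.arange(n)

    for i in range(n):
        train = np.delete(all_idx, i)
        Et = ws.E[train]
        R_tr = _subset_ranks(ws.E, ws.R_full, train, np.array([i]), ws.tied_cols)
        Z = _covariate_design(C[train])
        G = Z.T @ Z
        H = Z.T @ R_tr
        Bc = np.linalg.solve(G, H)
        css0 = ws.fold_rank_sumsq(R_tr)
        css = css0 - np.einsum("ij,ij->j", H, Bc)
        valid = css > 1e-10 * np.maximum(css0, 1.0)
        inv_sq_css = np.zeros(m)
        inv_sq_css[valid] = 1.0 / np.sqrt(css[valid])

        V = np.ascontiguousarray(Yp[:, train].T)  # (nt, B) raw training behavior
        Vr = _rank_columns_discrete(V)
        U = Vr - Z @ np.linalg.solve(G, Z.T @ Vr)
        uu = np.einsum("ij,ij->j", U, U)
        inv_uu = np.where(uu > 1e-12, 1.0 / np.sqrt(uu), 0.0)
        NUM = U.astype(dtype).T @ R_tr.astype(dtype)  # (B, m)
        RHO = NUM * (inv_sq_css.astype(dtype)[None, :])
        RHO *= inv_uu.astype(dtype)[:, None]

        mu_e, sd_e = ws.fold_edge_moments(np.array([i]))
        safe_sd = np.where(sd_e > 0, sd_e, 1.0)
        E_tz = (Et - mu_e) / safe_sd
        e_tez = (ws.E[i] - mu_e) / safe_sd
        mu_y = V.mean(axis=0)
        sd_y = V.std(axis=0, ddof=1)
        Yz = (V - mu_y) / sd_y  # (nt, B), columnwise mean exactly 0 up to fp
        actual_z = (Yp[:, i] - mu_y) / sd_y

        for tail in tails:
            mask = RHO > r_crit if tail == "positive" else RHO < -r_crit
            sel = sparse.csr_array(mask)  # (B, m) selection indicators
            S = sel @ E_tz.T  # (B, nt) training strengths
            s_te = sel @ e_tez  # (B,)
            s_bar = S.mean(axis=1)
            Sc = S - s_bar[:, None]
            var = np.einsum("ij,ij->i", Sc, Sc)
            cov = np.einsum("ij,ji->i", Sc, Yz)
            slope = np.where(var > 0, cov / np.maximum(var, 1e-300), 0.0)
            # training behavior is z-scored, so the intercept is -slope * s_bar
            p_hat = slope * (s_te - s_bar)
            pred[tail][:, i] = p_hat
            sqerr[tail] += (p_hat - actual_z) ** 2

    null_r = {t: np.empty(B) for t in tails}
    null_mse = {t: sqerr[t] / n for t in tails}
    for tail in tails:
        for b in range(B):
            null_r[tail][b] = _safe_spearman(pred[tail][b], Yp[b])[0]
    return null_r, null_mse


# ---------------------------------------------------------------------------
# Computational lesion analysis
# ---------------------------------------------------------------------------

@dataclass
class LesionReport:
    """Per-network lesioned performance vs the whole-brain model.

    ``table`` has one row per lesioned network: its size, the lesioned
    model's r, Steiger's Z against the whole-brain r, the one-tailed p, and
    the BH-FDR q across the lesion tests.
    """

    table: pd.DataFrame
    r_whole: float
    tail: str
    whole: "object"  # CpmResult
    lesioned: dict[str, "object"]


def lesion_analysis(
    connectomes: "Sequence[SubjectConnectome] | np.ndarray",
    behavior_table: pd.DataFrame,
    atlas: Atlas,
    config=None,
    *,
    networks: Sequence[str] | None = None,
    tail: str = "positive",
    whole_result=None,
) -> LesionReport:
    """Lesion each network in turn and compare predictions with Steiger's z.

    For every network: drop its nodes (and all incident edges), rerun the
    full LOOCV CPM — re-selection included — on the reduced edge set, assess,
    and test one-tailed whether the whole-brain r exceeds the lesioned r.
    The dependence between the two correlations is estimated from the
    Spearman correlation between the two prediction vectors.  BH-FDR is
    applied across the lesioned networks.
    """
    from .cpm_engine import CpmConfig, _EdgeWorkspace, _run_cv, prepare_data

    config = config or CpmConfig()
    if tail not in ("positive", "negative"):
        raise ValueError("tail must be 'positive' or 'negative'")
    data = prepare_data(connectomes, behavior_table, config)
    if data.edges.shape[1] != atlas.n_edges:
        raise ValueError("edge count does not match the atlas")
    ws = _EdgeWorkspace(data.edges)
    folds = [np.array([i]) for i in range(ws.n)]

    if whole_result is None:
        whole_result = _run_cv(ws, data.behavior, data.covariates, folds,
                               data.subject_ids, config, "loocv")
    r_whole = whole_result.assessment()[tail].r
    pred_whole = (whole_result.predicted_pos if tail == "positive"
                  else whole_result.predicted_neg)

    networks = tuple(networks) if networks is not None else atlas.networks
    n = data.edges.shape[0]
    rows, lesioned = [], {}
    for nw in networks:
        mask = lesion_edge_mask(atlas, nw)
        res = _run_cv(ws.subset_columns(mask), data.behavior, data.covariates,
                      folds, data.subject_ids, config, "loocv")
        lesioned[nw] = res
        a = res.assessment()[tail]
        pred_l = res.predicted_pos if tail == "positive" else res.predicted_neg
        r12, _ = _safe_spearman(pred_whole, pred_l)
        Z, p = steiger_compare(r_whole, a.r, r12, n)
        rows.append({"network": nw,
                     "n_nodes_removed": atlas.network_size(nw),
                     "r_lesion": a.r, "steiger_z": Z, "p_one_tailed": p})
    table = pd.DataFrame(rows)
    table["q_fdr"] = fdr_adjust(table["p_one_tailed"].to_numpy())
    return LesionReport(table=table, r_whole=float(r_whole), tail=tail,
                        whole=whole_result, lesioned=lesioned)
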
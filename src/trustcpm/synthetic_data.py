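"""Synthetic study datasets: atlas, connectomes, behavior, planted signal.

The generator emulates the study conditions the pipeline targets: ~101 older
adults, a 142-node five-network parcellation, one Fisher-z RSFC matrix per
subject, a discrete non-normal 0-10 trust score, and the four nuisance
covariates.  Trust propensity follows a binomial-logit model
``X ~ Binomial(10, p)``, ``logit(p) = a + b u`` with latent ``u ~ N(0,1)``,
whose constants are calibrated so the population mean and SD match the
reported 4.08 (2.41).  A configurable set of "signal" edges carries the
brain-behavior association: each planted edge is
``beta * z(X) + Normal(0, noise_sd)`` with ``beta`` chosen so its population
correlation with behavior equals ``edge_effect``; background edges are
i.i.d. normal on the Fisher-z scale.  Ground truth (planted indices and
effect) is recorded so recovery can be scored.

The default atlas fixture is a synthetic stand-in with the real
parcellation's network sizes (DMN 34, FPN 21, CON 32, SMN 33, OccN 22) and
plausible but fabricated node names and MNI coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas_connectome import (
    CEREBELLUM, NETWORK_SIZES, NETWORKS, Atlas, SubjectConnectome, compute_rsfc,
    devectorize_edges, edge_pairs, n_edges,
)

#: Binomial-logit constants giving population mean 4.08 and SD 2.41 for the
#: 0-10 trust score (solved from the model's Gauss-Hermite moments).
BEHAVIOR_LOGIT_A = -0.4421764
BEHAVIOR_LOGIT_B = 0.9427255


def default_atlas(include_cerebellum: bool = False, seed: int = 20240142) -> Atlas:
    """Synthetic 142-node/5-network atlas fixture (160 nodes with cerebellum).

    Node names and MNI coordinates are fabricated (seeded, deterministic);
    only the network partition and its sizes mirror the real parcellation.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(NETWORK_SIZES)
    if include_cerebellum:
        sizes[CEREBELLUM] = 18
    rows = []
    for nw, size in sizes.items():
        xyz = np.round(rng.uniform([-60, -90, -40], [60, 70, 70], size=(size, 3)))
        for k in range(size):
            rows.append({"name": f"{nw}_{k + 1:02d}",
                         "x": int(xyz[k, 0]), "y": int(xyz[k, 1]), "z": int(xyz[k, 2]),
                         "network": nw})
    return Atlas(pd.DataFrame(rows))


@dataclass
class SyntheticParams:
    """Study-condition parameters of the generator.

    Defaults mirror the emulated sample: n = 101 subjects; age 64.13 +/- 6.39
    years; education 11.17 +/- 3.21 years; P(female) = 0.69; head motion
    (mean framewise displacement, mm) log-normal with mean ~0.13, below the
    0.25 exclusion cut-off; 30 signal edges at per-edge correlation 0.4
    hosted in DMN + CON.  ``background_sd`` is the SD of null edges on the
    Fisher-z scale; ``edge_noise_sd`` the residual SD of planted edges.
    ``confounding`` optionally adds covariate terms (keyed by covariate
    name, per-SD logit coefficients) to the behavior model.
    """

    n_subjects: int = 101
    n_signal_edges: int = 30
    signal_networks: tuple[str, ...] = ("DMN", "CON")
    edge_effect: float = 0.4
    edge_noise_sd: float = 0.3
    background_sd: float = 0.3
    behavior_logit: tuple[float, float] = (BEHAVIOR_LOGIT_A, BEHAVIOR_LOGIT_B)
    age_mean: float = 64.13
    age_sd: float = 6.39
    education_mean: float = 11.17
    education_sd: float = 3.21
    p_female: float = 0.69
    fd_log_mean: float = -2.1
    fd_log_sd: float = 0.4
    confounding: dict[str, float] = field(default_factory=dict)
    confound_edge_sd: float = 0.1
    atlas: Atlas | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.edge_effect < 1.0:
            raise ValueError("edge_effect must lie in (-1, 1)")
        if self.n_signal_edges < 0:
            raise ValueError("n_signal_edges must be >= 0")
        unknown = set(self.signal_networks) - set(NETWORKS)
        if unknown:
            raise ValueError(f"unknown signal network(s): {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """A complete generated dataset plus its ground truth."""

    atlas: Atlas
    edges: np.ndarray  # n_subjects x n_edges, Fisher-z scale
    behavior: pd.DataFrame
    signal_edges: np.ndarray  # planted canonical edge indices
    edge_effect: float
    params: SyntheticParams

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.behavior["subject_id"]]

    def connectomes(self) -> list[SubjectConnectome]:
        """Materialize per-subject symmetric matrices from the edge vectors."""
        n = self.atlas.n_nodes
        return [SubjectConnectome(sid, devectorize_edges(row, n))
                for sid, row in zip(self.subject_ids, self.edges)]


def _behavior_moments(a: float, b: float, trials: int = 10) -> tuple[float, float]:
    """Population mean and SD of the binomial-logit trust score."""
    from numpy.polynomial.hermite_e import hermegauss

    nodes, w = hermegauss(80)
    w = w / w.sum()
    p = 1.0 / (1.0 + np.exp(-(a + b * nodes)))
    mean = trials * float(np.sum(w * p))
    ex2 = float(np.sum(w * (trials * p * (1 - p) + (trials * p) ** 2)))
    return mean, float(np.sqrt(ex2 - mean**2))


def _draw_covariates(params: SyntheticParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_subjects
    return pd.DataFrame({
        "age": rng.normal(params.age_mean, params.age_sd, n),
        "sex": rng.binomial(1, params.p_female, n).astype(float),
        "education": rng.normal(params.education_mean, params.education_sd, n),
        "fd": rng.lognormal(params.fd_log_mean, params.fd_log_sd, n),
    })


def generate_dataset(params: SyntheticParams | None = None, *,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset, reproducible from the seed.

    Behavior is drawn from the binomial-logit model (optionally confounded
    by covariates); the planted edges carry a common behavior-locked
    component sized so each edge's population correlation with the trust
    score is ``edge_effect``; every other edge is independent noise.
    """
    params = params or SyntheticParams()
    if seed is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    atlas = params.atlas if params.atlas is not None else default_atlas()
    n, m = params.n_subjects, n_edges(atlas.n_nodes)

    cov = _draw_covariates(params, rng)
    a, b = params.behavior_logit
    u = rng.standard_normal(n)
    logit = a + b * u
    confound = np.zeros(n)
    for name, coef in params.confounding.items():
        col = cov[name].to_numpy()
        sd = col.std()
        confound = confound + coef * (col - col.mean()) / (sd if sd > 0 else 1.0)
    logit = logit + confound
    p = 1.0 / (1.0 + np.exp(-logit))
    X = rng.binomial(10, p).astype(float)

    E = rng.normal(0.0, params.background_sd, size=(n, m))
    if params.confounding and params.confound_edge_sd > 0:
        # covariate-driven common signal leaks into every edge, so an
        # uncontrolled edge screen picks up spurious brain-behavior hits
        csd = confound.std()
        if csd > 0:
            E += params.confound_edge_sd * (confound / csd)[:, None]
    signal = _plant_edges(atlas, params, rng)
    if signal.size:
        mu, sd = _behavior_moments(a, b)
        xz = (X - mu) / sd
        rho = params.edge_effect
        beta = params.edge_noise_sd * rho / np.sqrt(1.0 - rho * rho)
        noise = rng.normal(0.0, params.edge_noise_sd, size=(n, signal.size))
        E[:, signal] = beta * xz[:, None] + noise

    behavior = pd.DataFrame({"subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
                             "trust": X})
    behavior["dictator"] = np.clip(
        np.round(9.26 + 2.37 * (0.28 * (X - X.mean()) / max(X.std(), 1e-9)
                                + np.sqrt(1 - 0.28**2) * rng.standard_normal(n))),
        0, 20)
    behavior = pd.concat([behavior, cov], axis=1)
    return SyntheticDataset(atlas=atlas, edges=E, behavior=behavior,
                            signal_edges=signal, edge_effect=params.edge_effect,
                            params=params)


def _plant_edges(atlas: Atlas, params: SyntheticParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Sample the planted edge indices among pairs within the host networks."""
    if params.n_signal_edges == 0:
        return np.empty(0, dtype=int)
    i, j = edge_pairs(atlas.n_nodes)
    host = np.isin(atlas.node_networks, params.signal_networks)
    eligible = np.flatnonzero(host[i] & host[j])
    if params.n_signal_edges > eligible.size:
        raise ValueError(
            f"cannot plant {params.n_signal_edges} edges in "
            f"{params.signal_networks}: only {eligible.size} pairs available")
    return np.sort(rng.choice(eligible, size=params.n_signal_edges, replace=False))


def null_params(**kwargs) -> SyntheticParams:
    """Convenience: parameters with no planted brain-behavior signal."""
    kwargs.setdefault("n_signal_edges", 0)
    return SyntheticParams(**kwargs)


def summarize_dataset(ds: SyntheticDataset) -> dict:
    """Mean/SD of behavior and covariates plus structural bookkeeping."""
    b = ds.behavior
    return {
        "n_subjects": len(b),
        "trust_mean": float(b["trust"].mean()),
        "trust_sd": float(b["trust"].std(ddof=1)),
        "dictator_mean": float(b["dictator"].mean()),
        "age_mean": float(b["age"].mean()),
        "education_mean": float(b["education"].mean()),
        "p_female": float(b["sex"].mean()),
        "fd_mean": float(b["fd"].mean()),
        "network_sizes": {nw: ds.atlas.network_size(nw) for nw in ds.atlas.networks},
        "n_edges": ds.edges.shape[1],
        "n_signal_edges": int(ds.signal_edges.size),
    }


def generate_time_series(
    atlas: Atlas, n_timepoints: int = 120, *, n_factors: int = 5,
    ar_coef: float = 0.3, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-node time courses with latent shared structure (for RSFC tests).

    Each node loads on a few latent temporal factors plus AR(1) noise, so the
    resulting correlation matrix has realistic off-diagonal spread.  This
    slower route exercises :func:`~trustcpm.atlas_connectome.compute_rsfc`
    end-to-end; the edge-level generator is the fast default.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = atlas.n_nodes
    factors = rng.standard_normal((n_timepoints, n_factors))
    loadings = rng.standard_normal((n_factors, n)) * 0.5
    noise = rng.standard_normal((n_timepoints, n))
    for t in range(1, n_timepoints):
        noise[t] += ar_coef * noise[t - 1]
    return factors @ loadings + noise
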
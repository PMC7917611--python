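"""MLLR and MAP adaptation of a trained gait HMM to a new subject.

A phase model trained on one group of walkers degrades on a new subject
whose angular-velocity levels differ (different age, build, cadence).
Both techniques re-estimate only the emission means and variances from a
small amount of unlabeled adaptation data, leaving the transition
structure, start distribution and mixture weights untouched:

* **MLLR** (maximum likelihood linear regression) estimates one global
  affine transform ``mu' = W [1; mu]`` shared by every Gaussian component,
  plus a diagonal variance scaling ``H``.  Because the transform is shared
  it can be estimated reliably from little data and moves even components
  that the adaptation data barely visits.
* **MAP** re-estimates each component separately, shrinking the
  occupancy-weighted sample statistics toward the prior with strength
  ``tau``; components the data never visits keep their prior values.

Chaining them — MLLR output as the MAP prior — combines the global shift
with component-level refinement where data is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hmm import (
    GaussianEmission,
    GmmEmission,
    HmmModel,
    forward_backward,
)

__all__ = ["MllrTransform", "MapConfig", "mllr_adapt", "map_adapt", "mllr_then_map"]


@dataclass
class MllrTransform:
    """Global mean transform W (d × d+1, acting on [1; mu]) and variance scaling H."""

    W: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if np.any(self.H <= 0):
            raise ValueError("variance scaling must be positive")

    @property
    def bias(self) -> np.ndarray:
        """The additive column of the transform."""
        return self.W[:, 0]


@dataclass(frozen=True)
class MapConfig:
    """MAP prior strength and which parameter groups to adapt."""

    tau: float = 10.0
    adapt_means: bool = True
    adapt_variances: bool = True

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")


# ---------------------------------------------------------------------------
# Component views: states (Gaussian) or state-mixture pairs (GMM) flattened
# to a list of (mean, diagonal variance) with per-frame occupancies.
# ---------------------------------------------------------------------------


def _component_params(model: HmmModel) -> tuple[np.ndarray, np.ndarray]:
    em = model.emission
    if isinstance(em, GaussianEmission):
        means = em.means.copy()
        variances = np.stack([np.diag(c).copy() for c in em.covs])
        return means, variances
    if isinstance(em, GmmEmission):
        d = em.dim
        return em.means.reshape(-1, d).copy(), em.variances.reshape(-1, d).copy()
    raise TypeError("adaptation requires Gaussian or GMM emissions")


def _component_occupancies(model: HmmModel, obs: np.ndarray) -> np.ndarray:
    post = forward_backward(model, obs)
    if isinstance(model.emission, GmmEmission):
        return post.eta.reshape(len(obs), -1)
    return post.gamma


def _set_component_means(model: HmmModel, means: np.ndarray) -> None:
    em = model.emission
    if isinstance(em, GaussianEmission):
        em.means = means.copy()
    else:
        em.means = means.reshape(em.means.shape).copy()


def _scale_component_variances(model: HmmModel, h: np.ndarray, floor: float) -> None:
    """Apply the diagonal scaling Sigma' = H^{1/2} Sigma H^{1/2} (PD-preserving)."""
    em = model.emission
    root = np.sqrt(h)
    if isinstance(em, GaussianEmission):
        em.covs = em.covs * np.outer(root, root)[None]
        for c in em.covs:
            c[np.diag_indices_from(c)] = np.maximum(np.diag(c), floor)
    else:
        em.variances = np.maximum(em.variances * h[None, None, :], floor)


def _set_component_variances(model: HmmModel, variances: np.ndarray, floor: float) -> None:
    em = model.emission
    variances = np.maximum(variances, floor)
    if isinstance(em, GaussianEmission):
        for i, c in enumerate(em.covs):
            # keep correlations, replace the diagonal scale
            old = np.sqrt(np.diag(c))
            corr = c / np.outer(old, old)
            new_sd = np.sqrt(variances[i])
            em.covs[i] = corr * np.outer(new_sd, new_sd)
    else:
        em.variances = variances.reshape(em.variances.shape)


def _data_floor(sequences: Sequence[np.ndarray], rel: float = 1e-8) -> float:
    allx = np.concatenate([np.asarray(s, dtype=float).reshape(len(s), -1) for s in sequences])
    return rel * float(np.max(allx.var(axis=0))) + 1e-300


def mllr_adapt(
    model: HmmModel,
    adaptation_sequences: Sequence[Sequence],
    n_em_iters: int = 3,
) -> tuple[HmmModel, MllrTransform]:
    """Global-transform MLLR: shared affine mean transform + variance scaling.

    Per EM iteration, component occupancies are computed on the adaptation
    data under the current model; the transform rows are then the solutions
    of occupancy-weighted normal equations (the diagonal-covariance closed
    form, with full covariances entering through their diagonals).  Rows
    whose design matrix is singular fall back to the identity with a
    warning.  Transitions and the start distribution are never changed.
    """
    if not adaptation_sequences:
        raise ValueError("need at least one adaptation sequence")
    adapted = model.copy()
    seqs = [np.asarray(s, dtype=float) for s in adaptation_sequences]
    seqs = [s.reshape(len(s), -1) for s in seqs]
    floor = _data_floor(seqs)
    d = seqs[0].shape[1]
    _, base_var = _component_params(model)
    # Composite transform relative to the *unadapted* model; per-iteration
    # transforms are composed so the returned W maps the original means.
    M_total = np.eye(d)
    b_total = np.zeros(d)
    H_total = np.ones(d)

    for _ in range(n_em_iters):
        means, variances = _component_params(adapted)
        ext = np.hstack([np.ones((len(means), 1)), means])  # (C, d+1)
        occ = np.zeros(len(means))
        wsum = np.zeros((len(means), d))  # sum_t gamma_tc * o_t
        wsq = np.zeros((len(means), d))  # sum_t gamma_tc * o_t**2
        for s in seqs:
            g = _component_occupancies(adapted, s)
            occ += g.sum(axis=0)
            wsum += g.T @ s
            wsq += g.T @ s**2

        # Mean transform: one row per output dimension.
        W = np.empty((d, d + 1))
        for q in range(d):
            inv_var = 1.0 / variances[:, q]
            G = (ext * (occ * inv_var)[:, None]).T @ ext
            k = (inv_var * wsum[:, q]) @ ext
            try:
                W[q] = np.linalg.solve(G, k)
            except np.linalg.LinAlgError:
                warnings.warn(f"MLLR design matrix singular for dimension {q}; "
                              "keeping identity row")
                W[q] = 0.0
                W[q, q + 1] = 1.0
        new_means = ext @ W.T
        _set_component_means(adapted, new_means)
        b_iter, M_iter = W[:, 0], W[:, 1:]
        b_total = M_iter @ b_total + b_iter
        M_total = M_iter @ M_total

        # Variance scaling from residual moments around the new means.
        total = occ.sum()
        if total > 0:
            resid = wsq - 2 * new_means * wsum + occ[:, None] * new_means**2
            H_iter = np.maximum((resid / variances).sum(axis=0) / total, 1e-12)
            H_total *= H_iter
        scaled = np.maximum(base_var * H_total[None, :], floor)
        _set_component_variances(adapted, scaled, floor)

    W_total = np.hstack([b_total[:, None], M_total])
    return adapted, MllrTransform(W=W_total, H=H_total)


def map_adapt(
    prior: HmmModel,
    adaptation_sequences: Sequence[Sequence],
    config: MapConfig = MapConfig(),
) -> HmmModel:
    """MAP re-estimation of emission means/variances with prior strength tau.

    With component occupancies gamma on the adaptation data,

        mu'    = (tau mu0 + sum_t gamma_t o_t) / (tau + sum_t gamma_t)
        Sigma' = (tau Sigma0 + sum_t gamma_t (o_t - mu')(o_t - mu')^T)
                 / (tau + sum_t gamma_t)

    so each adapted mean lies on the segment between the prior mean and the
    occupancy-weighted data mean.  Zero-occupancy components keep their
    prior values; transitions, start distribution and mixture weights are
    unchanged.
    """
    if not adaptation_sequences:
        raise ValueError("need at least one adaptation sequence")
    adapted = prior.copy()
    seqs = [np.asarray(s, dtype=float).reshape(len(np.asarray(s)), -1)
            for s in adaptation_sequences]
    floor = _data_floor(seqs)
    tau = config.tau

    means0, variances0 = _component_params(prior)
    occ = np.zeros(len(means0))
    wsum = np.zeros_like(means0)
    wsq = np.zeros_like(means0)
    for s in seqs:
        g = _component_occupancies(prior, s)
        occ += g.sum(axis=0)
        wsum += g.T @ s
        wsq += g.T @ s**2

    denom = (tau + occ)[:, None]
    new_means = (tau * means0 + wsum) / denom if config.adapt_means else means0.copy()
    if config.adapt_variances:
        resid = wsq - 2 * new_means * wsum + occ[:, None] * new_means**2
        new_vars = (tau * variances0 + resid) / denom
    else:
        new_vars = variances0.copy()

    _set_component_means(adapted, new_means)
    _set_component_variances(adapted, new_vars, floor)
    return adapted


def mllr_then_map(
    model: HmmModel,
    adaptation_sequences: Sequence[Sequence],
    config: MapConfig = MapConfig(),
    n_em_iters: int = 3,
) -> HmmModel:
    """MLLR first, then MAP with the MLLR-adapted model as the prior.

    The global transform absorbs the bulk of the subject shift even for
    rarely visited components; MAP then pulls well-observed components the
    rest of the way toward the subject's statistics.
    """
    adapted, _ = mllr_adapt(model, adaptation_sequences, n_em_iters=n_em_iters)
    return map_adapt(adapted, adaptation_sequences, config=config)
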
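"""Hidden Markov models with discrete, Gaussian and Gaussian-mixture emissions.

The gait model is a circular left-to-right chain: each of the four phase
states may persist or advance to the next phase, and the last phase wraps
back to the first, mirroring the cyclic structure of walking.  The module
implements the scaled forward-backward recursions, Viterbi decoding,
Baum-Welch (EM) parameter estimation for all three emission families, and
ancestral-sampling simulation, plus JSON serialisation.

All probability recursions use per-time normalisation of the forward and
backward variables, so likelihoods are returned in log space and sequences
of arbitrary length neither underflow nor overflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DiscreteEmission",
    "GaussianEmission",
    "GmmEmission",
    "HmmModel",
    "Posteriors",
    "circular_left_right_topology",
    "forward_backward",
    "viterbi",
    "loglikelihood",
    "fit_baum_welch",
    "simulate",
    "estimate_cycle_length",
    "initial_model",
    "supervised_initial_model",
    "jitter_model",
    "align_states_by_means",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Emission families
# ---------------------------------------------------------------------------


@dataclass
class DiscreteEmission:
    """Per-state categorical table ``probs[state, symbol]``."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be (n_states, n_symbols)")

    kind = "discrete"

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.probs.shape[1]

    def _symbols(self, obs: np.ndarray) -> np.ndarray:
        sym = np.asarray(obs)
        if sym.ndim == 2:
            sym = sym[:, 0]
        sym = sym.astype(int)
        if sym.min() < 0 or sym.max() >= self.n_symbols:
            raise ValueError("observation symbol outside emission table")
        return sym

    def log_density(self, obs: np.ndarray) -> np.ndarray:
        sym = self._symbols(obs)
        with np.errstate(divide="ignore"):
            return np.log(self.probs[:, sym].T)

    def sample(self, state: int, rng: np.random.Generator) -> np.ndarray:
        return np.array([rng.choice(self.n_symbols, p=self.probs[state])])

    def m_step(self, obs: np.ndarray, gamma: np.ndarray, floor: float) -> None:
        sym = self._symbols(obs)
        new = np.zeros_like(self.probs)
        np.add.at(new.T, sym, gamma)
        denom = gamma.sum(axis=0)
        ok = denom > 0
        new[ok] /= denom[ok, None]
        new[~ok] = self.probs[~ok]
        self.probs = new

    def copy(self) -> "DiscreteEmission":
        return DiscreteEmission(self.probs.copy())

    def to_dict(self) -> dict:
        return {"kind": self.kind, "probs": self.probs.tolist()}


@dataclass
class GaussianEmission:
    """One full-covariance Gaussian per state."""

    means: np.ndarray  # (N, d)
    covs: np.ndarray  # (N, d, d)

    kind = "gaussian"

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        covs = np.asarray(self.covs, dtype=float)
        if covs.ndim == 1:  # per-state scalar variances (1-D observations)
            covs = covs[:, None, None]
        self.covs = covs

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_density(self, obs: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(obs, dtype=float))
        if x.shape[1] != self.dim:
            x = x.reshape(-1, self.dim)
        out = np.empty((len(x), self.n_states))
        for i in range(self.n_states):
            chol = np.linalg.cholesky(self.covs[i])
            diff = x - self.means[i]
            sol = np.linalg.solve(chol, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, i] = -0.5 * (self.dim * _LOG2PI + logdet + maha)
        return out

    def sample(self, state: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.means[state], self.covs[state])

    def m_step(self, obs: np.ndarray, gamma: np.ndarray, floor: float) -> None:
        x = np.atleast_2d(np.asarray(obs, dtype=float)).reshape(len(gamma), self.dim)
        occ = gamma.sum(axis=0)
        global_mean = x.mean(axis=0)
        global_var = x.var(axis=0) + floor
        for i in range(self.n_states):
            if occ[i] <= 1e-10:
                warnings.warn(
                    f"state {i} has near-zero occupancy; reinitialising from "
                    "global statistics"
                )
                self.means[i] = global_mean
                self.covs[i] = np.diag(global_var)
                continue
            w = gamma[:, i]
            mu = w @ x / occ[i]
            diff = x - mu
            cov = (w[:, None] * diff).T @ diff / occ[i]
            # clip, don't add: the floor must leave healthy solutions exact
            # or the EM trace loses monotonicity
            d_idx = np.diag_indices(self.dim)
            cov[d_idx] = np.maximum(cov[d_idx], floor)
            self.means[i] = mu
            self.covs[i] = cov

    def copy(self) -> "GaussianEmission":
        return GaussianEmission(self.means.copy(), self.covs.copy())

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
        }


@dataclass
class GmmEmission:
    """Per-state diagonal-covariance Gaussian mixture.

    ``weights[j, m]`` is the prior of mixture component m in state j;
    each state has the same number of components M.
    """

    weights: np.ndarray  # (N, M)
    means: np.ndarray  # (N, M, d)
    variances: np.ndarray  # (N, M, d) diagonal covariances

    kind = "gmm"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)

    @property
    def n_states(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.means.shape[2]

    def component_log_density(self, obs: np.ndarray) -> np.ndarray:
        """Log N(o_t | mu_jm, Sigma_jm) for every (t, state, component)."""
        x = np.atleast_2d(np.asarray(obs, dtype=float)).reshape(-1, self.dim)
        diff = x[:, None, None, :] - self.means[None]  # (T, N, M, d)
        quad = np.sum(diff**2 / self.variances[None], axis=-1)
        logdet = np.sum(np.log(self.variances), axis=-1)  # (N, M)
        return -0.5 * (self.dim * _LOG2PI + logdet[None] + quad)

    def log_density(self, obs: np.ndarray) -> np.ndarray:
        comp = self.component_log_density(obs)
        with np.errstate(divide="ignore"):
            return logsumexp(comp + np.log(self.weights)[None], axis=2)

    def sample(self, state: int, rng: np.random.Generator) -> np.ndarray:
        m = rng.choice(self.n_components, p=self.weights[state])
        return rng.normal(self.means[state, m], np.sqrt(self.variances[state, m]))

    def m_step(self, obs: np.ndarray, eta: np.ndarray, floor: float) -> None:
        """Update weights/means/variances from state-component posteriors eta."""
        x = np.atleast_2d(np.asarray(obs, dtype=float)).reshape(len(eta), self.dim)
        occ = eta.sum(axis=0)  # (N, M)
        state_occ = occ.sum(axis=1)  # (N,)
        global_mean = x.mean(axis=0)
        global_var = x.var(axis=0) + floor
        for j in range(self.n_states):
            if state_occ[j] <= 1e-10:
                warnings.warn(
                    f"state {j} has near-zero occupancy; reinitialising from "
                    "global statistics"
                )
                self.weights[j] = 1.0 / self.n_components
                self.means[j] = global_mean
                self.variances[j] = global_var
                continue
            self.weights[j] = occ[j] / state_occ[j]
            for m in range(self.n_components):
                if occ[j, m] <= 1e-10:
                    continue
                w = eta[:, j, m]
                mu = w @ x / occ[j, m]
                var = w @ (x - mu) ** 2 / occ[j, m]
                self.means[j, m] = mu
                self.variances[j, m] = np.maximum(var, floor)

    def copy(self) -> "GmmEmission":
        return GmmEmission(
            self.weights.copy(), self.means.copy(), self.variances.copy()
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }


def emission_from_dict(d: dict):
    kind = d["kind"]
    if kind == "discrete":
        return DiscreteEmission(np.asarray(d["probs"]))
    if kind == "gaussian":
        return GaussianEmission(np.asarray(d["means"]), np.asarray(d["covs"]))
    if kind == "gmm":
        return GmmEmission(
            np.asarray(d["weights"]),
            np.asarray(d["means"]),
            np.asarray(d["variances"]),
        )
    raise ValueError(f"unknown emission kind {kind!r}")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


def circular_left_right_topology(n_states: int, allow_wrap: bool = True) -> np.ndarray:
    """Boolean mask of allowed transitions: self-loops, i→i+1, and N→1 if wrapping.

    Walking cycles through its phases in a fixed order with no skips, so the
    chain is left-to-right; the wrap entry lets one model span many cycles.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    mask = np.zeros((n_states, n_states), dtype=bool)
    idx = np.arange(n_states)
    mask[idx, idx] = True
    mask[idx[:-1], idx[:-1] + 1] = True
    if allow_wrap:
        mask[n_states - 1, 0] = True
    return mask


@dataclass
class HmmModel:
    """A hidden Markov model: start distribution, transitions, emissions.

    ``topology_mask`` pins structural zeros of the transition matrix; the
    mask is enforced at construction and preserved by every EM update.
    """

    pi: np.ndarray
    transitions: np.ndarray
    emission: DiscreteEmission | GaussianEmission | GmmEmission
    topology_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        n = len(self.pi)
        if self.transitions.shape != (n, n):
            raise ValueError("transition matrix shape must match pi")
        if self.topology_mask is None:
            self.topology_mask = self.transitions > 0
        self.topology_mask = np.asarray(self.topology_mask, dtype=bool)
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.transitions[~self.topology_mask] != 0.0):
            raise ValueError("transition matrix nonzero outside topology mask")
        if self.emission.n_states != n:
            raise ValueError("emission family sized for a different state count")

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def copy(self) -> "HmmModel":
        return HmmModel(
            self.pi.copy(),
            self.transitions.copy(),
            self.emission.copy(),
            self.topology_mask.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "pi": self.pi.tolist(),
            "transitions": self.transitions.tolist(),
            "topology_mask": self.topology_mask.astype(int).tolist(),
            "emission": self.emission.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(
            pi=np.asarray(d["pi"]),
            transitions=np.asarray(d["transitions"]),
            emission=emission_from_dict(d["emission"]),
            topology_mask=np.asarray(d["topology_mask"], dtype=bool),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "HmmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


@dataclass
class Posteriors:
    """Smoothed posteriors of one sequence under one model.

    ``gamma[t, i]`` is P(state_t = i | O); ``xi[t, i, j]`` is
    P(state_t = i, state_{t+1} = j | O); for mixture emissions
    ``eta[t, i, m]`` splits gamma across mixture components.  ``scaling``
    holds the per-time log normalisers whose sum is the log-likelihood.
    """

    log_likelihood: float
    gamma: np.ndarray
    xi: np.ndarray
    eta: np.ndarray | None = None
    scaling: np.ndarray | None = None


def _frame_logprobs(model: HmmModel, obs: np.ndarray) -> np.ndarray:
    logb = model.emission.log_density(obs)
    if not np.all(np.isfinite(np.asarray(obs, dtype=float))):
        raise ValueError("observations contain non-finite values")
    return logb


def _scaled_forward_backward(
    model: HmmModel, logb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-time-normalised alpha/beta; returns (alpha, beta, log_c, loglik)."""
    T, N = logb.shape
    A = model.transitions
    offsets = logb.max(axis=1)
    with np.errstate(invalid="ignore"):  # -inf - -inf when no state can emit
        b = np.exp(logb - offsets[:, None])  # rescaled emission likelihoods

    alpha = np.empty((T, N))
    log_c = np.empty(T)
    a = model.pi * b[0]
    c = a.sum()
    if c == 0.0 or not np.isfinite(c):
        raise FloatingPointError(
            "total likelihood underflowed to zero; consider raising the "
            "variance floor or rescaling features"
        )
    alpha[0] = a / c
    log_c[0] = np.log(c) + offsets[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c = a.sum()
        if c == 0.0 or not np.isfinite(c):
            raise FloatingPointError(
                "total likelihood underflowed to zero; consider raising the "
                "variance floor or rescaling features"
            )
        alpha[t] = a / c
        log_c[t] = np.log(c) + offsets[t]

    beta = np.empty((T, N))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / np.exp(log_c[t + 1] - offsets[t + 1])
    return alpha, beta, log_c, float(log_c.sum())


def forward_backward(model: HmmModel, obs: Sequence) -> Posteriors:
    """Scaled forward-backward pass returning log-likelihood, gamma, xi (, eta)."""
    obs = np.asarray(obs)
    logb = _frame_logprobs(model, obs)
    T, N = logb.shape
    alpha, beta, log_c, loglik = _scaled_forward_backward(model, logb)

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.empty((max(T - 1, 0), N, N))
    if T > 1:
        A = model.transitions
        offsets = logb.max(axis=1)
        b = np.exp(logb - offsets[:, None])
        for t in range(T - 1):
            m = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :]
            xi[t] = m / m.sum()

    eta = None
    if isinstance(model.emission, GmmEmission):
        comp = model.emission.component_log_density(obs)
        with np.errstate(divide="ignore"):
            logw = np.log(model.emission.weights)
        log_state = logsumexp(comp + logw[None], axis=2)
        resp = np.exp(comp + logw[None] - log_state[:, :, None])
        eta = gamma[:, :, None] * resp

    return Posteriors(
        log_likelihood=loglik, gamma=gamma, xi=xi, eta=eta, scaling=log_c
    )


def loglikelihood(model: HmmModel, obs: Sequence) -> float:
    """Log P(O | model) via the scaled forward pass."""
    logb = _frame_logprobs(model, np.asarray(obs))
    return _scaled_forward_backward(model, logb)[3]


def viterbi(model: HmmModel, obs: Sequence) -> tuple[np.ndarray, float]:
    """Most probable state path (0-based indices) and its log-probability.

    Ties during backtracking resolve to the lowest state index.
    """
    obs = np.asarray(obs)
    logb = _frame_logprobs(model, obs)
    T, N = logb.shape
    with np.errstate(divide="ignore"):
        logA = np.log(model.transitions)
        logpi = np.log(model.pi)
    delta = logpi + logb[0]
    back = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)  # argmax returns first (lowest) index
        delta = scores[back[t], np.arange(N)] + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    logp = float(delta[path[-1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, logp


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def fit_baum_welch(
    init: HmmModel,
    sequences: Sequence[Sequence],
    tol: float = 1e-6,
    max_iter: int = 200,
    fit_pi: bool = False,
    variance_floor: float = 1e-6,
) -> tuple[HmmModel, list[float]]:
    """Baum-Welch EM over one or more observation sequences.

    Sufficient statistics are pooled across sequences.  The transition
    update keeps the topology mask's structural zeros; the start
    distribution is frozen by default (gait recordings always begin in the
    heel-off state) and re-estimated only when ``fit_pi`` is set.  Returns
    the fitted model and the log-likelihood trace, which is non-decreasing
    up to numerical tolerance.

    ``variance_floor`` is relative to the per-dimension data variance and
    guards Gaussian/GMM components against collapse onto single points.
    """
    if not sequences:
        raise ValueError("need at least one training sequence")
    model = init.copy()
    seqs = [np.asarray(s) for s in sequences]
    is_gmm = isinstance(model.emission, GmmEmission)
    is_discrete = isinstance(model.emission, DiscreteEmission)
    if is_discrete:
        floor = 0.0
        all_obs = np.concatenate([s.reshape(len(s), -1) for s in seqs])
    else:
        all_obs = np.concatenate([s.reshape(len(s), -1) for s in seqs])
        floor = variance_floor * float(np.max(all_obs.var(axis=0))) + 1e-300

    trace: list[float] = []
    N = model.n_states
    for _ in range(max_iter):
        total_ll = 0.0
        xi_sum = np.zeros((N, N))
        gamma_trans = np.zeros(N)
        pi_acc = np.zeros(N)
        gammas = []
        etas = []
        for s in seqs:
            post = forward_backward(model, s)
            total_ll += post.log_likelihood
            pi_acc += post.gamma[0]
            if len(post.xi):
                xi_sum += post.xi.sum(axis=0)
                gamma_trans += post.gamma[:-1].sum(axis=0)
            gammas.append(post.gamma)
            if is_gmm:
                etas.append(post.eta)
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break

        # M-step
        if fit_pi:
            model.pi = pi_acc / len(seqs)
        A = np.zeros((N, N))
        ok = gamma_trans > 0
        A[ok] = xi_sum[ok] / gamma_trans[ok, None]
        A[~ok] = model.transitions[~ok]
        A[~model.topology_mask] = 0.0
        rows = A.sum(axis=1)
        good = rows > 0
        A[good] /= rows[good, None]
        A[~good] = model.transitions[~good]
        model.transitions = A

        gamma_all = np.concatenate(gammas)
        if is_gmm:
            model.emission.m_step(all_obs, np.concatenate(etas), floor)
        else:
            model.emission.m_step(all_obs, gamma_all, floor)

    return model, trace


# ---------------------------------------------------------------------------
# Simulation and initialisation helpers
# ---------------------------------------------------------------------------


def simulate(
    model: HmmModel, n_samples: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sampling: returns (observations, 0-based state sequence)."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    states = np.empty(n_samples, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.pi)
    for t in range(1, n_samples):
        states[t] = rng.choice(model.n_states, p=model.transitions[states[t - 1]])
    obs = np.stack([np.atleast_1d(model.emission.sample(s, rng)) for s in states])
    return obs, states


def estimate_cycle_length(sequence: Sequence, min_lag: int = 2) -> int | None:
    """Dominant period (in frames) of a quasi-periodic sequence.

    Uses the first convincing local maximum of the autocorrelation of the
    first feature dimension.  Returns None when no periodicity is found.
    """
    x = np.asarray(sequence, dtype=float).reshape(len(sequence), -1)[:, 0]
    x = x - x.mean()
    if len(x) < 2 * min_lag + 2 or not x.any():
        return None
    ac = np.correlate(x, x, "full")[len(x) - 1 :]
    ac /= ac[0]
    for lag in range(max(min_lag, 2), len(ac) - 1):
        if ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > 0.2:
            return lag
    return None


def initial_model(
    sequences: Sequence[Sequence],
    n_states: int = 4,
    emission: str = "gaussian",
    n_components: int = 1,
    allow_wrap: bool = True,
    start_state: int = 0,
    seed: int | None = None,
    jitter: float = 0.0,
    n_symbols: int | None = None,
    cycle_length: int | None = None,
) -> HmmModel:
    """Initialise an HMM from uniform-duration segmentation of the sequences.

    Each segmentation unit is cut into ``n_states`` contiguous equal parts
    and part k seeds the emission moments of state k, so state order
    follows temporal order.  For periodic data the unit should be one
    cycle: pass ``cycle_length`` (frames per cycle, e.g. from
    :func:`estimate_cycle_length`) and every cycle contributes its k-th
    segment to state k; without it the whole sequence is the unit, which
    only orders states for single-cycle recordings.  Transitions start
    uniform on the circular left-to-right mask and the start distribution
    is a point mass on ``start_state``.  ``jitter`` adds seeded Gaussian
    noise to the initial means (in units of the per-state standard
    deviation) to break symmetry across restarts.
    """
    rng = np.random.default_rng(seed)
    mask = circular_left_right_topology(n_states, allow_wrap)
    A = np.where(mask, 1.0, 0.0)
    A /= A.sum(axis=1, keepdims=True)
    pi = np.zeros(n_states)
    pi[start_state] = 1.0

    seqs = [np.asarray(s, dtype=float).reshape(len(s), -1) for s in sequences]
    units: list[np.ndarray] = []
    for s in seqs:
        if cycle_length and cycle_length >= n_states:
            for a in range(0, len(s) - cycle_length + 1, cycle_length):
                units.append(s[a : a + cycle_length])
        else:
            units.append(s)
    parts: list[list[np.ndarray]] = [[] for _ in range(n_states)]
    for u in units:
        bounds = np.linspace(0, len(u), n_states + 1).astype(int)
        for k in range(n_states):
            parts[k].append(u[bounds[k] : bounds[k + 1]])
    pooled = [np.concatenate(p) for p in parts]
    em = _emission_from_groups(pooled, emission, n_components, rng, jitter, n_symbols)
    return HmmModel(pi=pi, transitions=A, emission=em, topology_mask=mask)


def _emission_from_groups(
    pooled: list[np.ndarray],
    emission: str,
    n_components: int,
    rng: np.random.Generator,
    jitter: float,
    n_symbols: int | None,
):
    """Build an emission family from per-state sample groups (moment matching)."""
    n_states = len(pooled)
    dim = pooled[0].shape[1]
    if emission == "discrete":
        if n_symbols is None:
            n_symbols = int(max(p.max() for p in pooled)) + 1
        probs = np.empty((n_states, n_symbols))
        for k, p in enumerate(pooled):
            counts = np.bincount(p[:, 0].astype(int), minlength=n_symbols) + 1.0
            probs[k] = counts / counts.sum()
        return DiscreteEmission(probs)
    if emission == "gaussian":
        means = np.stack([p.mean(axis=0) for p in pooled])
        covs = np.stack(
            [np.atleast_2d(np.cov(p.T)) + 1e-6 * np.eye(dim) for p in pooled]
        )
        if jitter:
            means += jitter * np.sqrt(np.stack([p.var(axis=0) for p in pooled])) * (
                rng.standard_normal(means.shape)
            )
        return GaussianEmission(means, covs)
    if emission == "gmm":
        weights = np.full((n_states, n_components), 1.0 / n_components)
        means = np.empty((n_states, n_components, dim))
        variances = np.empty((n_states, n_components, dim))
        for k, p in enumerate(pooled):
            mu, sd = p.mean(axis=0), p.std(axis=0) + 1e-12
            # spread components along a ladder of the pooled spread
            offsets = np.linspace(-1, 1, n_components)[:, None]
            means[k] = mu + 0.5 * offsets * sd
            if jitter:
                means[k] += jitter * sd * rng.standard_normal((n_components, dim))
            variances[k] = np.maximum(p.var(axis=0), 1e-6)
        return GmmEmission(weights, means, variances)
    raise ValueError(f"unknown emission family {emission!r}")


def supervised_initial_model(
    sequences: Sequence[Sequence],
    label_sequences: Sequence[Sequence[int]],
    n_states: int = 4,
    emission: str = "gaussian",
    n_components: int = 1,
    allow_wrap: bool = True,
    start_state: int = 0,
    n_symbols: int | None = None,
) -> HmmModel:
    """Bootstrap an HMM from labeled frames (1-based state labels).

    Emission moments come from the frames of each state and the transition
    matrix from consecutive-label counts restricted to the circular
    left-to-right mask — the flat-start alternative for annotated training
    data, after which Baum-Welch refines all parameters on the likelihood.
    """
    mask = circular_left_right_topology(n_states, allow_wrap)
    seqs = [np.asarray(s, dtype=float).reshape(len(s), -1) for s in sequences]
    labs = [np.asarray(l, dtype=int) for l in label_sequences]
    if len(seqs) != len(labs) or any(len(s) != len(l) for s, l in zip(seqs, labs)):
        raise ValueError("label sequences must align with observation sequences")
    allx = np.concatenate(seqs)
    alll = np.concatenate(labs)
    pooled = []
    for k in range(1, n_states + 1):
        grp = allx[alll == k]
        pooled.append(grp if len(grp) >= 2 else allx)
    rng = np.random.default_rng(0)
    em = _emission_from_groups(pooled, emission, n_components, rng, 0.0, n_symbols)

    counts = np.zeros((n_states, n_states))
    for l in labs:
        np.add.at(counts, (l[:-1] - 1, l[1:] - 1), 1.0)
    counts[~mask] = 0.0
    A = np.where(mask, 1.0, 0.0)
    rows = counts.sum(axis=1)
    ok = rows > 0
    A[ok] = counts[ok] / rows[ok, None]
    A[~ok] /= A[~ok].sum(axis=1, keepdims=True)
    pi = np.zeros(n_states)
    pi[start_state] = 1.0
    return HmmModel(pi=pi, transitions=A, emission=em, topology_mask=mask)


def jitter_model(
    model: HmmModel,
    seed: int | np.random.Generator = 0,
    mean_scale: float = 0.5,
    var_log_sd: float = 0.3,
    transition_mix: float = 0.5,
) -> HmmModel:
    """Perturbed copy of a model, for parameter-recovery experiments.

    Means are shifted by seeded Gaussian noise of ``mean_scale`` state
    standard deviations, variances scaled by a lognormal factor, and
    transition rows mixed with the uniform distribution on the topology
    mask.  The start distribution and topology are untouched.
    """
    rng = np.random.default_rng(seed)
    out = model.copy()
    uniform = np.where(out.topology_mask, 1.0, 0.0)
    uniform /= uniform.sum(axis=1, keepdims=True)
    out.transitions = (1 - transition_mix) * out.transitions + transition_mix * uniform
    em = out.emission
    if isinstance(em, GaussianEmission):
        sd = np.sqrt(np.stack([np.diag(c) for c in em.covs]))
        em.means = em.means + mean_scale * sd * rng.standard_normal(em.means.shape)
        em.covs = em.covs * np.exp(rng.normal(0.0, var_log_sd, em.n_states))[
            :, None, None
        ]
    elif isinstance(em, GmmEmission):
        sd = np.sqrt(em.variances)
        em.means = em.means + mean_scale * sd * rng.standard_normal(em.means.shape)
        em.variances = em.variances * np.exp(
            rng.normal(0.0, var_log_sd, em.variances.shape)
        )
    elif isinstance(em, DiscreteEmission):
        noisy = em.probs * np.exp(rng.normal(0.0, var_log_sd, em.probs.shape))
        em.probs = noisy / noisy.sum(axis=1, keepdims=True)
    return out


def _emission_means(model: HmmModel) -> np.ndarray:
    em = model.emission
    if isinstance(em, GaussianEmission):
        return em.means
    if isinstance(em, GmmEmission):
        return np.einsum("jm,jmd->jd", em.weights, em.means)
    raise TypeError("nearest-mean alignment needs a continuous emission family")


def align_states_by_means(fitted: HmmModel, reference: HmmModel) -> np.ndarray:
    """Permutation p with p[k] = fitted state matching reference state k.

    Matching minimises total Euclidean distance between emission means
    (Hungarian assignment), which resolves the label-switching ambiguity of
    unsupervised fits.
    """
    from scipy.optimize import linear_sum_assignment

    mf = _emission_means(fitted)
    mr = _emission_means(reference)
    cost = np.linalg.norm(mr[:, None, :] - mf[None, :, :], axis=-1)
    _, cols = linear_sum_assignment(cost)
    return cols
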
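"""Four-state hidden Markov model of hourly movement behaviour.

Observations per interval: square-root step length (gamma emission with
a per-state point mass at exactly zero) and absolute turning angle
(Weibull emission truncated and renormalized over (0, pi], signs
symmetric).  State switching probabilities depend on solar time of day
through a first-harmonic cosinor in a multinomial-logit link.

States are labelled, in increasing order of mean step length:
rest (1), non-flight (2), local flight (3), migratory flight (4).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

log = logging.getLogger(__name__)

STATE_LABELS = ("rest", "non-flight", "local flight", "migratory flight")

_TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# forward / Viterbi kernels (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _forward_py(delta, gamma_stack, emis):
    T, S = emis.shape
    alpha = delta * emis[0]
    c = alpha.sum()
    if c <= 0.0:
        return -np.inf
    alpha /= c
    ll = math.log(c)
    for t in range(1, T):
        alpha = (alpha @ gamma_stack[t - 1]) * emis[t]
        c = alpha.sum()
        if c <= 0.0:
            return -np.inf
        alpha /= c
        ll += math.log(c)
    return ll


def _viterbi_py(log_delta, log_gamma_stack, log_emis):
    T, S = log_emis.shape
    back = np.zeros((T, S), dtype=np.int64)
    v = log_delta + log_emis[0]
    for t in range(1, T):
        vn = np.empty(S)
        for j in range(S):
            best, arg = -np.inf, 0
            for i in range(S):
                cand = v[i] + log_gamma_stack[t - 1, i, j]
                if cand > best:  # strict: ties keep the lower index
                    best, arg = cand, i
            vn[j] = best + log_emis[t, j]
            back[t, j] = arg
        v = vn
    path = np.zeros(T, dtype=np.int64)
    best, arg = -np.inf, 0
    for j in range(S):
        if v[j] > best:
            best, arg = v[j], j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _forward = njit(cache=False)(_forward_py)
    _viterbi = njit(cache=False)(_viterbi_py)
except Exception:  # pragma: no cover
    _forward = _forward_py
    _viterbi = _viterbi_py


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class HmmParams:
    """Natural-scale parameters of the movement HMM.

    ``beta`` has shape ``(S, S, 3)``: for each ordered off-diagonal
    pair (i, j) an intercept and coefficients of cos(2*pi*h/24) and
    sin(2*pi*h/24); the diagonal is the multinomial-logit reference and
    is ignored.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    step_zero_mass: np.ndarray
    angle_shape: np.ndarray
    angle_scale: np.ndarray
    beta: np.ndarray
    delta: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.step_mean)

    def validate(self) -> None:
        for name in ("step_mean", "step_sd", "angle_shape", "angle_scale"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must be finite and positive")
        if np.any(self.step_zero_mass < 0) or np.any(self.step_zero_mass >= 1):
            raise ValueError("step_zero_mass must lie in [0, 1)")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if not math.isclose(float(self.delta.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("delta must sum to 1")

    def transition_matrix(self, solar_hour: float) -> np.ndarray:
        """Row-stochastic transition matrix at the given solar hour."""
        return _transition_stack(self.beta, np.atleast_1d(float(solar_hour)))[0]

    def permute(self, perm: np.ndarray) -> "HmmParams":
        """Relabel states: new state k is old state ``perm[k]``."""
        perm = np.asarray(perm)
        return HmmParams(
            step_mean=self.step_mean[perm],
            step_sd=self.step_sd[perm],
            step_zero_mass=self.step_zero_mass[perm],
            angle_shape=self.angle_shape[perm],
            angle_scale=self.angle_scale[perm],
            beta=self.beta[np.ix_(perm, perm)],
            delta=self.delta[perm],
        )

    def to_json(self) -> str:
        doc = {
            "format": "phenotrack-hmm-params",
            "version": 1,
            "n_states": self.n_states,
            "state_labels": list(STATE_LABELS[: self.n_states]),
            **{
                k: getattr(self, k).tolist()
                for k in (
                    "step_mean",
                    "step_sd",
                    "step_zero_mass",
                    "angle_shape",
                    "angle_scale",
                    "beta",
                    "delta",
                )
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HmmParams":
        doc = json.loads(text)
        if doc.get("format") != "phenotrack-hmm-params":
            raise ValueError("not a phenotrack HMM parameter document")
        return cls(
            **{
                k: np.asarray(doc[k], dtype=float)
                for k in (
                    "step_mean",
                    "step_sd",
                    "step_zero_mass",
                    "angle_shape",
                    "angle_scale",
                    "beta",
                    "delta",
                )
            }
        )


@dataclass
class HmmConfig:
    """Model structure and optimizer settings for :func:`fit_hmm`."""

    n_states: int = 4
    time_varying: bool = True  # cosinor effect of solar hour on switching
    estimate_zero_mass: bool | None = None  # None: enabled iff zeros present
    maxiter: int = 500
    gtol: float = 1e-8
    ftol: float = 1e-8
    n_restarts: int = 5


@dataclass
class HmmFit:
    params: HmmParams
    loglik: float
    converged: bool
    restart_logliks: list = field(default_factory=list)
    message: str = ""


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _gamma_logpdf(x, mean, sd):
    """log N(k, theta) gamma density, (mean, sd) parameterization."""
    k = (mean / sd) ** 2
    theta = sd * sd / mean
    return (k - 1.0) * np.log(x) - x / theta - gammaln(k) - k * np.log(theta)


def _halfweibull_logpdf(a, shape, scale):
    """log density of |turn angle| on (0, pi]: Weibull renormalized, sign 1/2."""
    z = a / scale
    with np.errstate(divide="ignore"):
        logpdf = np.log(shape / scale) + (shape - 1.0) * np.log(z) - z**shape
        log_norm = np.log1p(-np.exp(-((np.pi / scale) ** shape)))
    return logpdf - log_norm + math.log(0.5)


def _emission_from_arrays(x: np.ndarray, a: np.ndarray, p: HmmParams) -> np.ndarray:
    T, S = len(x), p.n_states
    E = np.ones((T, S))

    obs_x = np.isfinite(x)
    pos = obs_x & (x > 0)
    zero = obs_x & (x == 0)
    obs_a = np.isfinite(a) & (a > 0)

    for s in range(S):
        if pos.any():
            E[pos, s] *= (1.0 - p.step_zero_mass[s]) * np.exp(
                _gamma_logpdf(x[pos], p.step_mean[s], p.step_sd[s])
            )
        if zero.any():
            E[zero, s] *= p.step_zero_mass[s]
        if obs_a.any():
            E[obs_a, s] *= np.exp(
                _halfweibull_logpdf(a[obs_a], p.angle_shape[s], p.angle_scale[s])
            )
    return E


def emission_matrix(obs: pd.DataFrame, p: HmmParams) -> np.ndarray:
    """Per-interval, per-state emission densities (T, S).

    Missing observations contribute a factor of 1, which marginalizes
    them out of the likelihood.
    """
    x = obs["sqrt_step"].to_numpy(dtype=float)
    a = np.abs(obs["turn_angle"].to_numpy(dtype=float))
    return _emission_from_arrays(x, a, p)


def _transition_stack(beta: np.ndarray, hours: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrices for an array of solar hours.

    Hours that are NaN fall back to the intercept-only matrix.
    """
    S = beta.shape[0]
    h = np.asarray(hours, dtype=float)
    c = np.where(np.isfinite(h), np.cos(_TWO_PI * h / 24.0), 0.0)
    s_ = np.where(np.isfinite(h), np.sin(_TWO_PI * h / 24.0), 0.0)
    eta = (
        beta[None, :, :, 0]
        + c[:, None, None] * beta[None, :, :, 1]
        + s_[:, None, None] * beta[None, :, :, 2]
    )
    idx = np.arange(S)
    eta[:, idx, idx] = 0.0  # diagonal is the logit reference
    eta -= eta.max(axis=2, keepdims=True)
    g = np.exp(eta)
    g /= g.sum(axis=2, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# likelihood / decoding
# ---------------------------------------------------------------------------

def hmm_forward_loglik(obs: pd.DataFrame, p: HmmParams) -> float:
    """Exact forward-algorithm log-likelihood of one observation stream."""
    p.validate()
    E = emission_matrix(obs, p)
    hours = obs["solar_hour"].to_numpy(dtype=float)
    # transition t-1 -> t evaluated at the covariate of the arrival interval
    G = _transition_stack(p.beta, hours[1:]) if len(hours) > 1 else np.empty(
        (0, p.n_states, p.n_states)
    )
    return float(_forward(p.delta.astype(float), G, E))


def viterbi_decode(obs: pd.DataFrame, p: HmmParams) -> np.ndarray:
    """Most probable state path (1-based states), ties to lower index."""
    p.validate()
    with np.errstate(divide="ignore"):
        logE = np.log(emission_matrix(obs, p))
        hours = obs["solar_hour"].to_numpy(dtype=float)
        G = _transition_stack(p.beta, hours[1:]) if len(hours) > 1 else np.empty(
            (0, p.n_states, p.n_states)
        )
        logG = np.log(G)
        logd = np.log(p.delta.astype(float))
    path = _viterbi(logd, logG, logE)
    return np.asarray(path) + 1


def label_states(p: HmmParams) -> np.ndarray:
    """Permutation ``perm`` with ``perm[k]`` = fitted state for label k.

    Labels are ordered by increasing gamma mean of the square-root step
    length; exact ties are broken by increasing angle scale (less
    directed movement later) and reported.
    """
    means = p.step_mean
    if len(np.unique(means)) < len(means):
        warnings.warn("tied step means; breaking ties by angle scale")
    order = np.lexsort((p.angle_scale, means))
    return order


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _pack(p: HmmParams, cfg: HmmConfig) -> np.ndarray:
    parts = [
        np.log(p.step_mean),
        np.log(p.step_sd),
        np.log(p.angle_shape),
        np.log(p.angle_scale),
    ]
    if cfg.estimate_zero_mass:
        zm = np.clip(p.step_zero_mass, 1e-12, 1 - 1e-12)
        parts.append(np.log(zm / (1 - zm)))
    S = cfg.n_states
    off = ~np.eye(S, dtype=bool)
    parts.append(p.beta[off][:, 0])
    if cfg.time_varying:
        parts.append(p.beta[off][:, 1:].ravel())
    d = np.clip(p.delta, 1e-12, None)
    parts.append(np.log(d[1:] / d[0]))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, cfg: HmmConfig) -> HmmParams:
    S = cfg.n_states
    i = 0

    def take(n):
        nonlocal i
        out = theta[i : i + n]
        i += n
        return out

    step_mean = np.exp(take(S))
    step_sd = np.exp(take(S))
    angle_shape = np.exp(take(S))
    angle_scale = np.exp(take(S))
    if cfg.estimate_zero_mass:
        zm = 1.0 / (1.0 + np.exp(-take(S)))
    else:
        zm = np.zeros(S)
    off = ~np.eye(S, dtype=bool)
    beta = np.zeros((S, S, 3))
    b0 = take(S * (S - 1))
    beta[off] = np.column_stack([b0, np.zeros_like(b0), np.zeros_like(b0)])
    if cfg.time_varying:
        bc = take(2 * S * (S - 1)).reshape(S * (S - 1), 2)
        tmp = beta[off]
        tmp[:, 1:] = bc
        beta[off] = tmp
    eta = np.concatenate([[0.0], take(S - 1)])
    delta = np.exp(eta - eta.max())
    delta /= delta.sum()
    return HmmParams(step_mean, step_sd, zm, angle_shape, angle_scale, beta, delta)


class _StreamData:
    """Pre-extracted arrays for one observation stream.

    The transition covariate usually takes few distinct values (hourly
    sampling), so transition matrices are built per unique hour and
    gathered, which dominates fitting speed.
    """

    def __init__(self, obs: pd.DataFrame):
        self.x = obs["sqrt_step"].to_numpy(dtype=float)
        self.a = np.abs(obs["turn_angle"].to_numpy(dtype=float))
        hours = obs["solar_hour"].to_numpy(dtype=float)[1:]
        self.unique_hours, self.hour_inverse = np.unique(
            np.round(hours, 9), return_inverse=True
        )

    def transition_stack(self, beta: np.ndarray) -> np.ndarray:
        return _transition_stack(beta, self.unique_hours)[self.hour_inverse]


def _pooled_negloglik(theta, streams, cfg):
    try:
        p = _unpack(theta, cfg)
    except (ValueError, FloatingPointError):
        return 1e12
    with np.errstate(over="ignore", invalid="ignore"):
        total = 0.0
        for sd in streams:
            E = _emission_from_arrays(sd.x, sd.a, p)
            if not np.all(np.isfinite(E)):
                return 1e12
            G = sd.transition_stack(p.beta)
            ll = _forward(p.delta.astype(float), G, E)
            if not np.isfinite(ll):
                return 1e12
            total += ll
    return -total


def _initial_params(streams, cfg: HmmConfig, rng: np.random.Generator, perturb: bool):
    """Quantile-based starting values, optionally jittered for restarts."""
    S = cfg.n_states
    x = np.concatenate([sd.x for sd in streams])
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < S:
        raise ValueError("too few positive steps to initialize")
    qs = np.quantile(x, np.linspace(0, 1, S + 1))
    means, sds = np.empty(S), np.empty(S)
    for s in range(S):
        grp = x[(x >= qs[s]) & (x <= qs[s + 1])]
        means[s] = max(grp.mean(), 1e-6)
        sds[s] = max(grp.std(), means[s] * 0.2)
    shape = np.linspace(0.8, 1.2, S)
    scale = np.full(S, 1.0)
    zm = np.full(S, 0.05)
    beta = np.zeros((S, S, 3))
    beta[..., 0] = -2.0
    delta = np.full(S, 1.0 / S)
    if perturb:
        means *= np.exp(rng.normal(0, 0.3, S))
        sds *= np.exp(rng.normal(0, 0.3, S))
        shape *= np.exp(rng.normal(0, 0.2, S))
        scale *= np.exp(rng.normal(0, 0.2, S))
        beta[..., 0] += rng.normal(0, 0.5, (S, S))
        if cfg.time_varying:
            beta[..., 1:] = rng.normal(0, 0.1, (S, S, 2))
    return HmmParams(means, sds, zm, shape, scale, beta, delta)


def fit_hmm(
    obs_list: list[pd.DataFrame],
    config: HmmConfig | None = None,
    seeds: list[int] | None = None,
) -> HmmFit:
    """Maximize the pooled log-likelihood over all observation streams.

    A quasi-Newton optimizer runs from one quantile-based start plus one
    jittered restart per seed; the best converged solution wins.  The
    returned parameters are relabelled so that state means increase.
    """
    cfg = config or HmmConfig()
    if isinstance(obs_list, pd.DataFrame):
        obs_list = [obs_list]
    if cfg.estimate_zero_mass is None:
        has_zeros = any(
            np.any(o["sqrt_step"].to_numpy(dtype=float) == 0.0) for o in obs_list
        )
        cfg = replace(cfg, estimate_zero_mass=has_zeros)
    seeds = list(seeds) if seeds is not None else list(range(cfg.n_restarts))
    streams = [_StreamData(o) for o in obs_list]

    starts = [(_initial_params(streams, cfg, np.random.default_rng(0), False), None)]
    for sd in seeds:
        rng = np.random.default_rng(sd)
        starts.append((_initial_params(streams, cfg, rng, True), sd))

    best = None
    restart_lls = []
    for p0, sd in starts:
        theta0 = _pack(p0, cfg)
        res = minimize(
            _pooled_negloglik,
            theta0,
            args=(streams, cfg),
            method="L-BFGS-B",
            options={"maxiter": cfg.maxiter, "gtol": cfg.gtol, "ftol": cfg.ftol},
        )
        restart_lls.append((-res.fun, bool(res.success), sd))
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res, sd)

    ll, res, _ = best
    if not any(ok for _, ok, _ in restart_lls) and not res.success:
        log.warning("no HMM restart reported convergence: %s", res.message)
    params = _unpack(res.x, cfg)
    perm = label_states(params)
    params = params.permute(perm)
    sep = np.abs(np.diff(np.sort(params.step_mean))) / params.step_mean.max()
    if np.any(sep < 1e-3):
        warnings.warn("possible state collapse: two state means nearly equal")
    return HmmFit(
        params=params,
        loglik=float(ll),
        converged=bool(res.success),
        restart_logliks=restart_lls,
        message=str(res.message),
    )
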
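"""Multi-rater consensus estimation (STAPLE).

Expectation-maximisation over R binary masks: alternately estimate the
per-voxel posterior probability W that a voxel is true foreground
(E-step) and each rater's sensitivity p_j / specificity q_j (M-step).
Probabilities are computed in log space; p and q are clipped away from
{0, 1} so the likelihood stays finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["ConsensusResult", "StapleConfig", "staple", "staple_estep", "staple_mstep"]

EPS_CLIP = 1e-5


@dataclass
class ConsensusResult:
    W: np.ndarray                 # posterior foreground probability per voxel
    p: np.ndarray                 # per-rater sensitivity
    q: np.ndarray                 # per-rater specificity
    prevalence: float
    trace: list[float]            # observed-data log-likelihood per iteration
    iterations: int

    @property
    def consensus_mask(self) -> np.ndarray:
        # tie at 0.5 resolves to foreground
        return self.W >= 0.5

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "p": self.p.tolist(),
            "q": self.q.tolist(),
            "prevalence": self.prevalence,
            "iterations": self.iterations,
            "log_likelihood_trace": self.trace,
        }, indent=2))


@dataclass
class StapleConfig:
    prior_mode: str = "fixed"        # "fixed" | "estimated"
    pi0: float | None = None         # None → mean foreground fraction of raters
    init_p: float = 0.9999
    init_q: float = 0.9999
    tol: float = 1e-6
    max_iter: int = 100
    spatial_smoothing: str = "off"   # "off" | "meanfield"
    beta: float = 0.5                # mean-field mixing weight
    eps: float = EPS_CLIP

    def __post_init__(self):
        if self.prior_mode not in ("fixed", "estimated"):
            raise ValueError("prior_mode must be 'fixed' or 'estimated'")
        if self.spatial_smoothing not in ("off", "meanfield"):
            raise ValueError("spatial_smoothing must be 'off' or 'meanfield'")


def _stack(masks) -> np.ndarray:
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all rater masks must share a grid")
    return np.stack([a.ravel() for a in arrs], axis=0)  # (R, N)


def _clip(x: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(x, eps, 1.0 - eps)


def staple_estep(masks, p, q, prevalence) -> np.ndarray:
    """Posterior W_i from current rater performance estimates.

    a_i = π Π_j p^d (1-p)^(1-d);  b_i = (1-π) Π_j (1-q)^d q^(1-d);
    W_i = a_i / (a_i + b_i), evaluated in log space.  ``prevalence`` may
    be a scalar or a per-voxel array (spatial prior).
    """
    d = _stack(masks)
    p = _clip(np.asarray(p, dtype=float), EPS_CLIP)
    q = _clip(np.asarray(q, dtype=float), EPS_CLIP)
    pi = np.asarray(prevalence, dtype=float)
    pi_flat = pi.ravel() if pi.ndim else pi
    log_a = d.T @ np.log(p) + (1 - d).T @ np.log1p(-p)
    log_b = d.T @ np.log1p(-q) + (1 - d).T @ np.log(q)
    if np.ndim(pi_flat):
        pi_c = np.clip(pi_flat, EPS_CLIP, 1 - EPS_CLIP)
    else:
        pi_c = float(np.clip(pi_flat, EPS_CLIP, 1 - EPS_CLIP))
        if prevalence in (0.0, 1.0):  # exact degenerate priors short-circuit
            W = np.full(d.shape[1], float(prevalence))
            return W.reshape(np.asarray(masks[0]).shape)
    log_a = log_a + np.log(pi_c)
    log_b = log_b + np.log1p(-pi_c)
    m = np.maximum(log_a, log_b)
    a = np.exp(log_a - m)
    b = np.exp(log_b - m)
    W = a / (a + b)
    return W.reshape(np.asarray(masks[0]).shape)


def staple_mstep(masks, W, prior_mode: str = "fixed", eps: float = EPS_CLIP):
    """Update (p, q, π) from the posterior W.

    p_j = Σ W d / Σ W;  q_j = Σ (1-W)(1-d) / Σ (1-W); π = mean(W) only in
    'estimated' mode (otherwise returned as None and kept by the caller).
    """
    d = _stack(masks)
    w = np.asarray(W, dtype=float).ravel()
    sw = w.sum()
    swc = (1.0 - w).sum()
    if sw <= 0 or swc <= 0:
        raise ValueError("degenerate posterior: all-foreground or all-background W")
    p = _clip((d @ w) / sw, eps)
    q = _clip(((1 - d) @ (1.0 - w)) / swc, eps)
    pi = float(w.mean()) if prior_mode == "estimated" else None
    return p, q, pi


def _log_likelihood(d, p, q, pi):
    log_a = d.T @ np.log(p) + (1 - d).T @ np.log1p(-p) + np.log(pi)
    log_b = d.T @ np.log1p(-q) + (1 - d).T @ np.log(q) + np.log1p(-pi)
    m = np.maximum(log_a, log_b)
    return float(np.sum(m + np.log(np.exp(log_a - m) + np.exp(log_b - m))))


def staple(masks, config: StapleConfig | None = None) -> ConsensusResult:
    """Run STAPLE EM on R congruent binary masks.

    Stops when the max absolute change in W falls below ``config.tol`` or
    after ``config.max_iter`` iterations.  With a single rater the result
    is degenerate but still computed.  Raises for all-empty or all-full
    input (no information about the boundary).
    """
    config = config or StapleConfig()
    shape = np.asarray(masks[0]).shape
    d = _stack(masks)
    R, N = d.shape
    frac = d.mean(axis=1)
    if np.all(frac == 0) or np.all(frac == 1):
        raise ValueError("degenerate consensus: raters are all-empty or all-full")

    p = np.full(R, config.init_p)
    q = np.full(R, config.init_q)
    pi = float(np.mean(frac)) if config.pi0 is None else float(config.pi0)
    pi = float(np.clip(pi, config.eps, 1 - config.eps))

    W = None
    trace: list[float] = []
    iterations = 0
    for it in range(config.max_iter):
        trace.append(_log_likelihood(d, _clip(p, config.eps), _clip(q, config.eps), pi))
        if config.spatial_smoothing == "meanfield" and W is not None:
            local = ndimage.uniform_filter(W.reshape(shape), size=3).ravel()
            prior = (1 - config.beta) * pi + config.beta * local
            W_new = staple_estep(masks, p, q, prior.reshape(shape)).ravel()
        else:
            W_new = staple_estep(masks, p, q, pi).ravel()
        p, q, pi_new = staple_mstep(masks, W_new, config.prior_mode, config.eps)
        if pi_new is not None:
            pi = float(np.clip(pi_new, config.eps, 1 - config.eps))
        iterations = it + 1
        if W is not None and np.max(np.abs(W_new - W)) < config.tol:
            W = W_new
            break
        W = W_new

    return ConsensusResult(
        W=W.reshape(shape),
        p=p,
        q=q,
        prevalence=pi,
        trace=trace,
        iterations=iterations,
    )
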
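"""Sticky hidden Markov model segmentation of movement syllables.

Locomotor behavior (forward and left speed, centered and whitened) is
segmented with a 5-state Gaussian HMM, rearing (up speed) with a 3-state 1D
model.  Stickiness — a prior preference for self-transitions that discourages
fast syllable switching — enters both through the initialization
``T_init = (1 - eta) I + eta / n_states`` and through a sticky
pseudo-count prior on the transition rows.  The model is fit by
maximum-a-posteriori EM on fixed-length snippets that contribute sufficient
statistics jointly, with conjugate regularizers standing in for the
Dirichlet / Normal / LogNormal–LKJ priors: a Dirichlet-style pseudo-count
prior on transition rows and a normal–inverse-Wishart prior of matching scale
on the emissions.  The penalized objective is non-decreasing across EM
iterations by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import mannwhitneyu, spearmanr
from sklearn.cluster import KMeans

__all__ = ["HMMConfig", "StickyHMM", "Ethogram", "fit_sticky_hmm",
           "viterbi_decode", "bout_statistics", "simulate_hmm"]


@dataclass
class HMMConfig:
    eta: float = 0.05              # stickiness of the initial transition matrix
    dirichlet_conc: float = 0.5    # symmetric transition pseudo-count
    sticky_pseudocount: float = 10.0  # extra diagonal pseudo-count (regularizer)
    n_iter: int = 100
    tol: float = 1e-6
    snippet_len: int = 600         # frames per snippet
    # Emission prior (normal-inverse-Wishart surrogate, whitened units):
    kappa0: float = 1.0            # mean shrinkage toward 0 ~ Normal(0, 1)
    psi_scale: float = 0.1         # inverse-Wishart scale matrix Psi = psi * I
    seed: int = 0


@dataclass
class StickyHMM:
    n_states: int
    T: np.ndarray            # (K, K) row-stochastic transition matrix
    mu: np.ndarray           # (K, D) emission means
    S: np.ndarray            # (K, D, D) emission covariances
    pi: np.ndarray           # (K,) initial distribution
    eta: float = 0.05
    dirichlet_conc: float = 0.5
    log_objective: list = field(default_factory=list)
    reseeded: bool = False

    def __post_init__(self) -> None:
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_states": self.n_states, "T": self.T.tolist(),
            "mu": self.mu.tolist(), "S": self.S.tolist(),
            "pi": self.pi.tolist(), "eta": self.eta,
            "dirichlet_conc": self.dirichlet_conc,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "StickyHMM":
        d = json.loads(Path(path).read_text())
        return cls(d["n_states"], np.array(d["T"]), np.array(d["mu"]),
                   np.array(d["S"]), np.array(d["pi"]), d["eta"],
                   d["dirichlet_conc"])


@dataclass
class Ethogram:
    states: np.ndarray                    # (T,) most-likely state per frame
    bouts: list = field(default_factory=list)  # (state, start, end) frame spans
    frame_rate: float = 60.0

    def bout_durations(self, state: int) -> np.ndarray:
        """Bout durations of one state, in seconds."""
        return np.array([(e - s) / self.frame_rate
                         for st, s, e in self.bouts if st == state])

    def export_csv(self, path: str | Path) -> None:
        lines = ["state,start_frame,end_frame,duration_s"]
        for st, s, e in self.bouts:
            lines.append(f"{st},{s},{e},{(e - s) / self.frame_rate:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def sticky_transition_init(n_states: int, eta: float) -> np.ndarray:
    return (1.0 - eta) * np.eye(n_states) + eta / n_states


def _log_gauss(x: np.ndarray, mu: np.ndarray, S: np.ndarray) -> np.ndarray:
    """(T, K) log density of each frame under each state's Gaussian."""
    T, D = x.shape
    K = mu.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        diff = x - mu[k]
        chol = np.linalg.cholesky(S[k])
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (maha + logdet + D * np.log(2 * np.pi))
    return out


def _forward_backward(logB: np.ndarray, T_mat: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward; returns (loglik, gamma, xi_sum)."""
    Tn, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.empty((Tn, K))
    c = np.empty(Tn)
    alpha[0] = pi * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, Tn):
        alpha[t] = (alpha[t - 1] @ T_mat) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((Tn, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(Tn - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        xi = T_mat * np.outer(alpha[t], bb)
        xi_sum += xi / xi.sum()
        beta[t] = (T_mat @ bb) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = np.sum(np.log(c)) + np.sum(logB.max(axis=1))
    return loglik, gamma, xi_sum


def _emission_log_prior(mu: np.ndarray, S: np.ndarray, cfg: HMMConfig) -> float:
    """Log of the NIW-surrogate emission prior (up to a constant)."""
    K, D = mu.shape
    nu0 = D + 2.0
    total = 0.0
    for k in range(K):
        Sinv = np.linalg.inv(S[k])
        _, logdet = np.linalg.slogdet(S[k])
        total += -0.5 * cfg.kappa0 * mu[k] @ Sinv @ mu[k]
        total += -0.5 * (nu0 + D + 2.0) * logdet
        total += -0.5 * cfg.psi_scale * np.trace(Sinv)
    return total


_PI_PRIOR = 1e-3  # tiny Dirichlet pseudo-count keeping pi off the boundary


def _penalized_objective(loglik: float, model_T: np.ndarray, mu: np.ndarray,
                         S: np.ndarray, pi: np.ndarray,
                         prior_counts: np.ndarray, cfg: HMMConfig) -> float:
    return (loglik + float(np.sum(prior_counts * np.log(model_T)))
            + _PI_PRIOR * float(np.sum(np.log(pi)))
            + _emission_log_prior(mu, S, cfg))


def fit_sticky_hmm(speeds: np.ndarray, n_states: int,
                   config: HMMConfig | None = None) -> StickyHMM:
    """MAP-EM fit of the sticky Gaussian HMM to centered/whitened speeds."""
    config = config or HMMConfig()
    x = np.atleast_2d(np.asarray(speeds, dtype=float))
    if x.shape[1] > x.shape[0]:
        x = x.T
    if x.ndim != 2 or x.shape[1] not in (1, 2):
        raise ValueError("speeds must be (T,) or (T, 1..2)")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    T_len, D = x.shape

    km = KMeans(n_clusters=n_states, n_init=5, random_state=config.seed).fit(x)
    mu = km.cluster_centers_.copy()
    S = np.empty((n_states, D, D))
    for k in range(n_states):
        pts = x[km.labels_ == k]
        S[k] = np.cov(pts.T).reshape(D, D) if len(pts) > D else np.eye(D)
        S[k] += 1e-4 * np.eye(D)
    T_mat = sticky_transition_init(n_states, config.eta)
    pi = np.full(n_states, 1.0 / n_states)

    snippets = [x[i:i + config.snippet_len]
                for i in range(0, T_len, config.snippet_len)]
    snippets = [s for s in snippets if len(s) >= 2]
    prior_counts = (config.dirichlet_conc * np.ones((n_states, n_states))
                    + config.sticky_pseudocount * np.eye(n_states))
    nu0 = D + 2.0
    Psi = config.psi_scale * np.eye(D)
    rng = np.random.default_rng(config.seed)

    objective: list[float] = []
    reseeded = False
    for _ in range(config.n_iter):
        loglik = 0.0
        gamma_sum = np.zeros(n_states)
        gamma_x = np.zeros((n_states, D))
        gamma_xx = np.zeros((n_states, D, D))
        xi_total = np.zeros((n_states, n_states))
        pi_counts = np.zeros(n_states)
        for snip in snippets:
            logB = _log_gauss(snip, mu, S)
            ll, gamma, xi = _forward_backward(logB, T_mat, pi)
            loglik += ll
            gamma_sum += gamma.sum(axis=0)
            gamma_x += gamma.T @ snip
            gamma_xx += np.einsum("tk,ti,tj->kij", gamma, snip, snip)
            xi_total += xi
            pi_counts += gamma[0]
        objective.append(_penalized_objective(loglik, T_mat, mu, S, pi,
                                              prior_counts, config))

        if np.any(gamma_sum < 1e-8):
            if reseeded:
                break
            reseeded = True
            for k in np.flatnonzero(gamma_sum < 1e-8):
                mu[k] = x[rng.integers(0, T_len)]
                S[k] = np.eye(D)
            continue

        # M-step (exact MAP updates for the surrogate priors).
        T_mat = xi_total + prior_counts
        T_mat /= T_mat.sum(axis=1, keepdims=True)
        pi = pi_counts + _PI_PRIOR
        pi /= pi.sum()
        for k in range(n_states):
            Nk = gamma_sum[k]
            xbar = gamma_x[k] / Nk
            mu[k] = Nk * xbar / (config.kappa0 + Nk)
            scatter = gamma_xx[k] - Nk * np.outer(xbar, xbar)
            shrink = (config.kappa0 * Nk / (config.kappa0 + Nk)) * np.outer(xbar, xbar)
            S[k] = (Psi + scatter + shrink) / (nu0 + Nk + D + 2.0)
            S[k] = 0.5 * (S[k] + S[k].T)
        if len(objective) > 1 and abs(objective[-1] - objective[-2]) < config.tol * abs(objective[-2]):
            break
    return StickyHMM(n_states, T_mat, mu, S, pi, config.eta,
                     config.dirichlet_conc, objective, reseeded)


def viterbi_decode(model: StickyHMM, speeds: np.ndarray,
                   frame_rate: float = 60.0) -> Ethogram:
    """Most-likely state path (Viterbi) and its run-length-encoded bouts."""
    x = np.atleast_2d(np.asarray(speeds, dtype=float))
    if x.shape[1] > x.shape[0]:
        x = x.T
    logB = _log_gauss(x, model.mu, model.S)
    logT = np.log(model.T)
    Tn, K = logB.shape
    delta = np.log(model.pi) + logB[0]
    back = np.zeros((Tn, K), dtype=int)
    for t in range(1, Tn):
        cand = delta[:, None] + logT
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(Tn, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(Tn - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    bouts = []
    start = 0
    for t in range(1, Tn + 1):
        if t == Tn or path[t] != path[start]:
            bouts.append((int(path[start]), start, t))
            start = t
    return Ethogram(path, bouts, frame_rate)


def bout_statistics(ethogram: Ethogram, elevation: np.ndarray | None = None,
                    min_bouts: int = 2) -> dict:
    """Per-state bout-duration statistics and pairwise rank-sum tests.

    Returns duration lists and medians per state, two-sided Mann-Whitney
    U-tests between every state pair with at least ``min_bouts`` bouts each,
    and — when a per-frame body elevation is supplied — the Spearman rank
    correlation between bout-mean elevation and bout duration.
    """
    states = sorted({st for st, _, _ in ethogram.bouts})
    durations = {st: ethogram.bout_durations(st) for st in states}
    medians = {st: (float(np.median(d)) if len(d) else np.nan)
               for st, d in durations.items()}
    tests = {}
    skipped = []
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            if len(durations[a]) < min_bouts or len(durations[b]) < min_bouts:
                skipped.append((a, b))
                continue
            U, p = mannwhitneyu(durations[a], durations[b],
                                alternative="two-sided")
            tests[(a, b)] = {"U": float(U), "p": float(p)}
    out = {"durations": durations, "medians": medians, "tests": tests,
           "skipped": skipped}
    if elevation is not None:
        el, dur = [], []
        for st, s, e in ethogram.bouts:
            el.append(float(np.mean(elevation[s:e])))
            dur.append((e - s) / ethogram.frame_rate)
        rho, p = spearmanr(el, dur)
        out["elevation_duration_spearman"] = {"rho": float(rho), "p": float(p)}
    return out


def simulate_hmm(model: StickyHMM, n_frames: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample (states, emissions) from a sticky HMM — simulation oracle."""
    K, D = model.mu.shape
    states = np.empty(n_frames, dtype=int)
    x = np.empty((n_frames, D))
    states[0] = rng.choice(K, p=model.pi)
    for t in range(n_frames):
        if t > 0:
            states[t] = rng.choice(K, p=model.T[states[t - 1]])
        x[t] = rng.multivariate_normal(model.mu[states[t]], model.S[states[t]])
    return states, x
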
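"""Neural analysis: event-aligned PSTHs and multiplexed Poisson tuning models.

Two complementary analyses of spike trains recorded during social behavior:

* PSTH analysis aligned to detected social-touch events, with a "naive"
  variant (all events) and a "cleaned" variant that keeps only events with a
  quiet 4 s baseline, a paired pre/post rate comparison (two-tailed Wilcoxon
  signed-rank) and a bounded modulation index.

* A multiplicative tuning-curve model: the spike train is Poisson with rate
  ``lambda = exp(sum_p A_p c_p) / dt`` where each behavioral feature enters
  through a binned one-hot design matrix ``A_p`` and a tuning-curve vector
  ``c_p``.  Curves are fit by penalized maximum likelihood (first-difference
  smoothness penalty ``beta``, with circular wrap-around for angular
  features) using a Newton-CG trust-region method, and the features a neuron
  encodes are found by greedy forward selection under 10-fold (30-chunk)
  cross-validation with a one-sided signed-rank admission test.

The log-likelihood gain of a model over the constant-rate model is reported
in bits per spike.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import wilcoxon

from .behavior_features import FeatureMatrix

__all__ = [
    "SpikeTrain", "BinnedDesign", "TuningModel", "TuningConfig",
    "psth", "modulation_index", "poisson_penalized_loglik", "fit_tuning",
    "delta_loglik_bits_per_spike", "forward_select", "simulate_spikes",
    "co_encoding",
]

_EXP_CLAMP = 30.0  # max exponent in the rate nonlinearity


@dataclass
class SpikeTrain:
    unit_id: str
    times: np.ndarray       # sorted spike times, s
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if self.t_stop is None:
            self.t_stop = float(self.times[-1]) if len(self.times) else self.t_start
        if len(self.times) and (self.times[0] < self.t_start
                                or self.times[-1] > self.t_stop):
            raise ValueError("spike times outside session bounds")

    def bin_counts(self, dt: float, n_bins: int) -> np.ndarray:
        edges = self.t_start + dt * np.arange(n_bins + 1)
        counts, _ = np.histogram(self.times, bins=edges)
        return counts

    @classmethod
    def from_file(cls, path: str | Path, unit_id: str | None = None) -> "SpikeTrain":
        """Read spike times from a plain event-time file (one time per line)."""
        times = np.loadtxt(path, ndmin=1)
        return cls(unit_id or Path(path).stem, times)


# ---------------------------------------------------------------------------
# PSTH analysis
# ---------------------------------------------------------------------------

def psth(spikes: SpikeTrain, events: np.ndarray, mode: str = "naive",
         all_event_times: np.ndarray | None = None,
         pre_window: tuple[float, float] = (-4.0, -2.0),
         post_window: tuple[float, float] = (-0.5, 0.5),
         curve_window: tuple[float, float] = (-4.0, 4.0),
         curve_bin: float = 0.1, min_events: int = 5) -> dict:
    """Event-aligned PSTH with paired pre/post rate comparison.

    ``mode='cleaned'`` keeps only events with no other detected event in the
    4 s before onset (``all_event_times`` defaults to the aligned events
    themselves).  Baseline rate ``r_pre`` averages (-4, -2) s, response rate
    ``r_post`` averages (-0.5, 0.5) s; the two are compared per event with a
    two-tailed Wilcoxon signed-rank test.
    """
    events = np.sort(np.asarray(events, dtype=float))
    if mode not in ("naive", "cleaned"):
        raise ValueError("mode must be 'naive' or 'cleaned'")
    if mode == "cleaned":
        pool = np.sort(np.asarray(all_event_times if all_event_times is not None
                                  else events, dtype=float))
        keep = []
        for ev in events:
            prior = pool[(pool > ev - 4.0) & (pool < ev)]
            keep.append(len(prior) == 0)
        events = events[keep]
    under_powered = len(events) < min_events

    n_spikes = len(spikes.times)
    pre_dur = pre_window[1] - pre_window[0]
    post_dur = post_window[1] - post_window[0]
    r_pre_ev = np.array([np.sum((spikes.times >= ev + pre_window[0])
                                & (spikes.times < ev + pre_window[1])) / pre_dur
                         for ev in events])
    r_post_ev = np.array([np.sum((spikes.times >= ev + post_window[0])
                                 & (spikes.times < ev + post_window[1])) / post_dur
                          for ev in events])
    edges = np.arange(curve_window[0], curve_window[1] + curve_bin / 2, curve_bin)
    curve = np.zeros(len(edges) - 1)
    for ev in events:
        counts, _ = np.histogram(spikes.times - ev, bins=edges)
        curve += counts
    if len(events):
        curve /= len(events) * curve_bin

    r_pre = float(np.mean(r_pre_ev)) if len(events) else 0.0
    r_post = float(np.mean(r_post_ev)) if len(events) else 0.0
    if n_spikes == 0 or len(events) == 0 or np.all(r_pre_ev == r_post_ev):
        p = np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = wilcoxon(r_pre_ev, r_post_ev, alternative="two-sided")
    return {"curve": curve, "edges": edges, "r_pre": r_pre, "r_post": r_post,
            "p": float(p) if p == p else np.nan, "n_events": len(events),
            "under_powered": under_powered}


def modulation_index(r_pre: float, r_post: float) -> float:
    """(r_post - r_pre) / (r_post + r_pre); bounded in [-1, 1]."""
    if r_pre + r_post <= 0:
        raise ValueError("r_pre + r_post must be > 0")
    return (r_post - r_pre) / (r_post + r_pre)


# ---------------------------------------------------------------------------
# Binned design and penalized Poisson likelihood
# ---------------------------------------------------------------------------

@dataclass
class BinnedDesign:
    """One-hot binned predictors plus per-bin spike counts."""

    A: dict                   # feature name -> (T, n_bins) one-hot matrix
    edges: dict               # feature name -> bin edges
    circular: dict            # feature name -> bool
    counts: np.ndarray        # (T,) spike counts per time bin
    dt: float                 # s per time bin

    @property
    def names(self) -> list[str]:
        return list(self.A.keys())

    @classmethod
    def from_features(cls, features: FeatureMatrix, spikes: SpikeTrain,
                      dt: float = 1.0 / 60.0, n_bins: int = 10) -> "BinnedDesign":
        """Bin every feature column; circular features get circular bins.

        Linear features are binned over their observed range; masked (NaN)
        frames get all-zero design rows.
        """
        T = len(features.data)
        counts = spikes.bin_counts(dt, T)
        A, edges, circ = {}, {}, {}
        for name in features.names:
            vals = features.data[name].to_numpy(dtype=float)
            is_circ = name in features.circular
            if is_circ:
                e = np.linspace(-np.pi, np.pi, n_bins + 1)
            else:
                lo, hi = np.nanmin(vals), np.nanmax(vals)
                if hi <= lo:
                    hi = lo + 1e-9
                e = np.linspace(lo, hi, n_bins + 1)
            idx = np.clip(np.searchsorted(e, vals, side="right") - 1, 0, n_bins - 1)
            M = np.zeros((T, n_bins))
            ok = np.isfinite(vals)
            M[np.arange(T)[ok], idx[ok]] = 1.0
            A[name], edges[name], circ[name] = M, e, is_circ
        return cls(A, edges, circ, counts, dt)


def _difference_penalty(n_bins: int, circular: bool) -> np.ndarray:
    """Quadratic form L with c^T L c = sum_i (c_i - c_{i+1})^2."""
    L = np.zeros((n_bins, n_bins))
    last = n_bins if circular else n_bins - 1
    for i in range(last):
        j = (i + 1) % n_bins
        L[i, i] += 1.0
        L[j, j] += 1.0
        L[i, j] -= 1.0
        L[j, i] -= 1.0
    return L


def poisson_penalized_loglik(c: dict, design: BinnedDesign, beta: float
                             ) -> tuple[float, dict, callable]:
    """Penalized Poisson log-likelihood, gradient, and Hessian-vector product.

    Objective: ``sum_i n_i u_i - exp(u_i) - beta/2 sum_p ||D c_p||^2`` with
    ``u = sum_p A_p c_p`` (the expected count per bin is ``exp(u)``; the rate
    in Hz is ``exp(u)/dt``).  The smoothness penalty is the squared first
    difference of each curve, wrapping around for circular features.
    """
    u = np.zeros(len(design.counts))
    for name, cp in c.items():
        u = u + design.A[name] @ cp
    if np.any(u > _EXP_CLAMP):
        warnings.warn("rate exponent clamped to avoid overflow", stacklevel=2)
        u = np.minimum(u, _EXP_CLAMP)
    lam = np.exp(u)
    n = design.counts
    obj = float(np.sum(n * u - lam))
    grad = {}
    for name, cp in c.items():
        L = _difference_penalty(len(cp), design.circular[name])
        obj -= 0.5 * beta * float(cp @ L @ cp)
        grad[name] = design.A[name].T @ (n - lam) - beta * (L @ cp)

    def hessp(v: dict) -> dict:
        Av = np.zeros(len(n))
        for name, vp in v.items():
            Av = Av + design.A[name] @ vp
        w = lam * Av
        out = {}
        for name, vp in v.items():
            L = _difference_penalty(len(vp), design.circular[name])
            out[name] = -(design.A[name].T @ w) - beta * (L @ vp)
        return out

    return obj, grad, hessp


def _pack(c: dict, names: list[str]) -> np.ndarray:
    return np.concatenate([c[n] for n in names])


def _unpack(x: np.ndarray, design: BinnedDesign, names: list[str]) -> dict:
    out, pos = {}, 0
    for n in names:
        nb = design.A[n].shape[1]
        out[n] = x[pos:pos + nb]
        pos += nb
    return out


def fit_tuning(design: BinnedDesign, library: list[str], beta: float = 20.0,
               mask: np.ndarray | None = None, x0: np.ndarray | None = None,
               tol: float = 1e-3) -> dict:
    """Jointly fit the tuning curves of every feature in the library.

    Maximizes the penalized Poisson log-likelihood with a Newton-CG
    trust-region method (analytic gradient and Hessian-vector product).
    ``mask`` restricts the fit to a subset of time bins (for cross-
    validation).  Returns {"curves": dict, "converged": bool}.
    """
    if not library:
        raise ValueError("library must be non-empty")
    sub = design if mask is None else BinnedDesign(
        {k: v[mask] for k, v in design.A.items()}, design.edges,
        design.circular, design.counts[mask], design.dt)
    if sub.counts.sum() == 0:
        return {"curves": {n: np.full(sub.A[n].shape[1], -10.0) for n in library},
                "converged": False}
    names = list(library)
    size = sum(sub.A[n].shape[1] for n in names)

    def negobj(x):
        obj, grad, _ = poisson_penalized_loglik(_unpack(x, sub, names), sub, beta)
        return -obj, -_pack(grad, names)

    def neg_hessp(x, v):
        _, _, hp = poisson_penalized_loglik(_unpack(x, sub, names), sub, beta)
        return -_pack(hp(_unpack(v, sub, names)), names)

    res = minimize(negobj, x0 if x0 is not None else np.zeros(size),
                   jac=True, hessp=neg_hessp, method="trust-ncg",
                   tol=tol)
    return {"curves": _unpack(res.x, sub, names), "converged": bool(res.success)}


def _neg_loglik_per_spike(lam: np.ndarray, n: np.ndarray) -> float:
    """Negative Poisson log-likelihood per spike (nats), lam = expected counts."""
    lam = np.maximum(lam, 1e-12)
    return float(np.sum(lam - n * np.log(lam) + gammaln(n + 1)) / n.sum())


def delta_loglik_bits_per_spike(lam_model: np.ndarray, counts: np.ndarray
                                ) -> float:
    """Log-likelihood gain of a model over the constant-rate model, bits/spike.

    Both likelihoods are normalized by the total spike count; positive means
    the model beats the constant-rate (mean-count) model.
    """
    n = np.asarray(counts, dtype=float)
    if n.sum() <= 0:
        raise ValueError("need at least one spike")
    l_model = _neg_loglik_per_spike(np.asarray(lam_model, dtype=float), n)
    l_const = _neg_loglik_per_spike(np.full_like(n, n.mean()), n)
    return (l_const - l_model) / np.log(2.0)


def _predict_counts(c: dict, design: BinnedDesign,
                    mask: np.ndarray | None = None) -> np.ndarray:
    idx = slice(None) if mask is None else mask
    u = np.zeros(len(design.counts))
    for name, cp in c.items():
        u = u + design.A[name] @ cp
    return np.exp(np.minimum(u[idx], _EXP_CLAMP))


# ---------------------------------------------------------------------------
# Cross-validated greedy forward selection
# ---------------------------------------------------------------------------

@dataclass
class TuningConfig:
    beta: float = 20.0
    n_chunks: int = 30
    n_folds: int = 10
    alpha: float = 0.05
    max_features: int | None = None
    tol: float = 1e-3


@dataclass
class TuningModel:
    """Selected feature library and tuning curves of one neuron."""

    unit_id: str
    library: list              # selected feature names, in admission order
    curves: dict               # feature -> tuning-curve vector (full-data fit)
    edges: dict
    beta: float
    fold_gains: list           # per selection round: (10,) held-out bits/spike
    p_values: list             # per selection round
    history: list              # candidate chosen each round

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "unit_id": self.unit_id, "library": self.library,
            "curves": {k: v.tolist() for k, v in self.curves.items()},
            "edges": {k: np.asarray(v).tolist() for k, v in self.edges.items()},
            "beta": self.beta,
            "fold_gains": [list(map(float, g)) for g in self.fold_gains],
            "p_values": self.p_values, "history": self.history,
        }))


def _fold_masks(T: int, n_chunks: int, n_folds: int
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Interleaved chunk folds: chunk c belongs to fold c mod n_folds."""
    chunk_of = np.minimum(np.arange(T) * n_chunks // T, n_chunks - 1)
    folds = []
    for f in range(n_folds):
        test = (chunk_of % n_folds) == f
        folds.append((~test, test))
    return folds


def forward_select(design: BinnedDesign, config: TuningConfig | None = None,
                   unit_id: str = "unit") -> TuningModel:
    """Greedy cross-validated forward selection of encoded features.

    Each round fits every one-feature-larger model on the 27 training chunks
    of each of 10 interleaved folds (data split into 30 chunks), scores the
    held-out log-likelihood gain in bits/spike against the current model,
    picks the candidate with the highest mean gain, and admits it if a
    one-sided Wilcoxon signed-rank test across the folds is significant at
    ``alpha``.  Selection stops at the first non-significant candidate; an
    empty library is a valid outcome.
    """
    config = config or TuningConfig()
    T = len(design.counts)
    folds = _fold_masks(T, config.n_chunks, config.n_folds)
    library: list[str] = []
    fold_gains_hist, p_hist, history = [], [], []
    # Held-out gains of the current library per fold (0 for the constant model).
    base_gain = np.zeros(config.n_folds)
    max_feat = config.max_features or len(design.names)
    while len(library) < max_feat:
        candidates = [nm for nm in design.names if nm not in library]
        if not candidates:
            break
        cand_gain = np.zeros((len(candidates), config.n_folds))
        for ci, cand in enumerate(candidates):
            lib = library + [cand]
            for fi, (train, test) in enumerate(folds):
                fit = fit_tuning(design, lib, config.beta, mask=train,
                                 tol=config.tol)
                lam = _predict_counts(fit["curves"], design, test)
                if design.counts[test].sum() == 0:
                    cand_gain[ci, fi] = 0.0
                else:
                    cand_gain[ci, fi] = delta_loglik_bits_per_spike(
                        lam, design.counts[test])
        mean_gain = cand_gain.mean(axis=1)
        best = int(np.argmax(mean_gain))
        gains = cand_gain[best]
        diff = gains - base_gain
        if np.allclose(diff, 0):
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = wilcoxon(diff, alternative="greater")
        history.append(candidates[best])
        fold_gains_hist.append(gains)
        p_hist.append(float(p))
        if p >= config.alpha:
            break
        library.append(candidates[best])
        base_gain = gains
    curves = (fit_tuning(design, library, config.beta,
                         tol=config.tol)["curves"] if library else {})
    return TuningModel(unit_id, library, curves,
                       {k: design.edges[k] for k in library},
                       config.beta, fold_gains_hist, p_hist, history)


# ---------------------------------------------------------------------------
# Spike simulation and population structure
# ---------------------------------------------------------------------------

def simulate_spikes(design_A: dict, true_curves: dict, dt: float,
                    rng: np.random.Generator, t_start: float = 0.0,
                    unit_id: str = "sim") -> SpikeTrain:
    """Sample a spike train from the generative multiplicative tuning model.

    Per-bin counts are Poisson with mean ``exp(sum_p A_p c_p)``; spike times
    are jittered uniformly within their bin.
    """
    names = list(true_curves.keys())
    T = design_A[names[0]].shape[0] if names else 0
    u = np.zeros(T)
    for name in names:
        u = u + design_A[name] @ true_curves[name]
    counts = rng.poisson(np.exp(np.minimum(u, _EXP_CLAMP)))
    times = []
    for i in np.flatnonzero(counts):
        times.extend(t_start + (i + rng.random(counts[i])) * dt)
    return SpikeTrain(unit_id, np.array(times), t_start, t_start + T * dt)


def co_encoding(models: list[TuningModel], feature_names: list[str]
                ) -> tuple[pd.DataFrame, list[tuple[str, str, int]]]:
    """Population co-encoding matrix and its graph edge list.

    Entry (i, j) counts the neurons whose selected library contains both
    feature i and feature j; the diagonal holds per-feature counts.  The
    edge list (feature_i, feature_j, count) covers off-diagonal nonzeros and
    can be fed to any graph-layout tool.
    """
    if not models:
        raise ValueError("need at least one model")
    K = len(feature_names)
    index = {n: i for i, n in enumerate(feature_names)}
    M = np.zeros((K, K), dtype=int)
    for model in models:
        idx = [index[n] for n in model.library]
        for a in idx:
            for b in idx:
                M[a, b] += 1
    df = pd.DataFrame(M, index=feature_names, columns=feature_names)
    edges = [(feature_names[i], feature_names[j], int(M[i, j]))
             for i in range(K) for j in range(i + 1, K) if M[i, j] > 0]
    return df, edges
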
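"""Bounded random-walk Metropolis sampler with adaptive tuning.

All model parameters live in a box (0 <= pi <= 1; 0 <= mu, sigma, c <= 40;
0 < m <= 5), so a plain Gaussian random walk would waste proposals outside
the box.  The proposal is instead a per-coordinate Gaussian truncated to the
box.  Truncation makes the proposal asymmetric (the truncation normalizer
depends on the current position), so the Metropolis-Hastings acceptance ratio
carries an explicit correction term; without it the stationary distribution
is biased near the bounds.

Inference runs in three phases: an adaptive phase tuning the proposal scales
toward a target acceptance rate (Robbins-Monro stochastic approximation,
capped at ``adapt_max_iters``), a burn-in phase with frozen scales whose
draws are discarded, and a sampling phase.  Phase lengths are doubled for
eight-parameter two-condition fits.  With the default flat prior on the box,
the posterior is proportional to the likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp, ndtr, ndtri

from .model import (
    LN2,
    _LOG_SQRT_2PI,
    Dataset,
    _binom_logpmf,
    _log_expit,
    _survive,
)

__all__ = [
    "MCMCConfig",
    "Bounds",
    "Chain",
    "PosteriorSummary",
    "propose_truncated",
    "adapt_scales",
    "run_mcmc",
    "shortest_interval",
    "summarize",
    "autocorr_time",
    "make_loglik",
    "fit_single_condition",
    "fit_two_condition",
    "SINGLE_PARAM_NAMES",
    "TWO_CONDITION_PARAM_NAMES",
]

SINGLE_PARAM_NAMES = ("pi", "mu", "sigma", "c", "m")
TWO_CONDITION_PARAM_NAMES = (
    "pi_a", "mu_a", "sigma_a", "pi_b", "mu_b", "sigma_b", "c", "m",
)

SIGMA_FLOOR = 1e-3  # sampler's lower bound for sigma and m (degenerate at 0)


@dataclass
class MCMCConfig:
    """Phase lengths and tuning knobs of the three-phase sampler."""

    adapt_max_iters: int = 400_000
    burnin_iters: int = 20_000
    sample_iters: int = 200_000
    two_condition_multiplier: int = 2
    proposal_scales: np.ndarray | None = None
    target_acceptance: float = 0.234  # joint all-coordinate proposals
    seed: int | None = None
    thin: int = 1
    update_mode: str = "joint"  # "joint" | "per_coordinate" (target 0.44)
    adapt_window: int = 1000
    adapt_tol: float = 0.05
    adapt_stable_windows: int = 5

    def __post_init__(self) -> None:
        if min(self.adapt_max_iters, self.burnin_iters, self.sample_iters) < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.update_mode not in ("joint", "per_coordinate"):
            raise ValueError("update_mode must be 'joint' or 'per_coordinate'")


@dataclass(frozen=True)
class Bounds:
    """Per-parameter box constraints."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if not (self.lower < self.upper).all():
            raise ValueError("each lower bound must be < the upper bound")

    @property
    def dim(self) -> int:
        return len(self.lower)

    def contains(self, x) -> bool:
        x = np.asarray(x, dtype=float)
        return bool((x >= self.lower).all() and (x <= self.upper).all())

    @classmethod
    def single_condition(cls) -> "Bounds":
        return cls(
            [0.0, 0.0, SIGMA_FLOOR, 0.0, SIGMA_FLOOR],
            [1.0, 40.0, 40.0, 40.0, 5.0],
        )

    @classmethod
    def two_condition(cls) -> "Bounds":
        return cls(
            [0.0, 0.0, SIGMA_FLOOR, 0.0, 0.0, SIGMA_FLOOR, 0.0, SIGMA_FLOOR],
            [1.0, 40.0, 40.0, 1.0, 40.0, 40.0, 40.0, 5.0],
        )


@dataclass
class Chain:
    """Retained MCMC draws with phase bookkeeping and diagnostics."""

    draws: np.ndarray  # (n, d)
    logposts: np.ndarray  # (n,)
    acceptance_rate: float
    tuned_scales: np.ndarray
    bounds: Bounds
    param_names: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df["log_posterior"] = self.logposts
        return df


@dataclass
class PosteriorSummary:
    """Posterior mean, shortest 90% CrI and mode per parameter."""

    param_names: tuple[str, ...]
    mean: np.ndarray
    cri_lo: np.ndarray
    cri_hi: np.ndarray
    mode: np.ndarray  # highest-log-posterior draw
    autocorr_time: np.ndarray
    degenerate: np.ndarray  # per-parameter constant-chain flag
    mass: float = 0.9

    def to_dict(self) -> dict:
        return {
            name: {
                "mean": float(self.mean[i]),
                "cri_lo": float(self.cri_lo[i]),
                "cri_hi": float(self.cri_hi[i]),
                "mode": float(self.mode[i]),
                "autocorr_time": float(self.autocorr_time[i]),
            }
            for i, name in enumerate(self.param_names)
        }


# ---------------------------------------------------------------------------
# Proposal
# ---------------------------------------------------------------------------

def propose_truncated(
    current: np.ndarray,
    scales: np.ndarray,
    bounds: Bounds,
    rng: np.random.Generator,
):
    """Draw a truncated-Gaussian proposal and its log Hastings correction.

    Each coordinate is Gaussian centered at the current value, truncated to
    its bound interval.  Returns ``(proposal, log q(x|y) - log q(y|x))``:
    the truncation normalizers differ between the forward and reverse moves,
    so this correction must be added to the log-posterior difference in the
    accept/reject step.
    """
    current = np.asarray(current, dtype=float)
    if not bounds.contains(current):
        raise ValueError("current state outside bounds")
    lo, hi = bounds.lower, bounds.upper
    a = ndtr((lo - current) / scales)
    b = ndtr((hi - current) / scales)
    u = a + (b - a) * rng.random(len(current))
    # clip away from 0/1 for ndtri stability at extreme scales
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    proposal = current + scales * ndtri(u)
    proposal = np.clip(proposal, lo, hi)
    zb = ndtr((hi - proposal) / scales)
    za = ndtr((lo - proposal) / scales)
    log_corr = float(
        np.sum(np.log(np.maximum(b - a, 1e-300)) - np.log(np.maximum(zb - za, 1e-300)))
    )
    return proposal, log_corr


def _propose_coord(current, j, scale, bounds, rng):
    lo, hi = bounds.lower[j], bounds.upper[j]
    a = ndtr((lo - current[j]) / scale)
    b = ndtr((hi - current[j]) / scale)
    u = min(max(a + (b - a) * rng.random(), 1e-15), 1 - 1e-15)
    y = min(max(current[j] + scale * ndtri(u), lo), hi)
    zb = ndtr((hi - y) / scale)
    za = ndtr((lo - y) / scale)
    prop = current.copy()
    prop[j] = y
    return prop, float(math.log(b - a) - math.log(zb - za))


# ---------------------------------------------------------------------------
# Adaptive phase
# ---------------------------------------------------------------------------

@dataclass
class AdaptResult:
    scales: np.ndarray
    state: np.ndarray
    logpost: float
    acceptance_rate: float
    n_iters: int


def adapt_scales(
    logpost_fn: Callable[[np.ndarray], float],
    init: np.ndarray,
    bounds: Bounds,
    config: MCMCConfig,
    rng: np.random.Generator,
    max_iters: int | None = None,
    hastings_correction: bool = True,
) -> AdaptResult:
    """Robbins-Monro tuning of the proposal scales toward the target
    acceptance rate.

    The log-scales receive increments ``(alpha_t - target) / t**0.6`` where
    ``alpha_t`` is the acceptance probability of iteration t; adaptation
    stops early once the windowed acceptance rate has stayed within
    ``adapt_tol`` of the target for ``adapt_stable_windows`` consecutive
    windows, or at the iteration cap.  Returned scales are frozen.
    """
    x = np.asarray(init, dtype=float).copy()
    if not bounds.contains(x):
        raise ValueError("init outside bounds")
    lp = logpost_fn(x)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at init")
    scales = _init_scales(config, bounds)
    max_iters = config.adapt_max_iters if max_iters is None else max_iters
    if max_iters == 0:
        return AdaptResult(scales, x, lp, 0.0, 0)

    target = (
        0.44 if config.update_mode == "per_coordinate" else config.target_acceptance
    )
    # keep the walk a local move: scales beyond the box span degenerate into
    # near-uniform independence proposals and the tuner loses its signal
    span = bounds.upper - bounds.lower
    log_hi = np.log(span)
    log_lo = np.log(span) - 18.0
    d = bounds.dim
    win_acc = 0.0
    stable = 0
    n_acc = 0.0
    t = 0
    log_scales = np.log(scales)
    while t < max_iters:
        t += 1
        if config.update_mode == "joint":
            prop, corr = propose_truncated(x, np.exp(log_scales), bounds, rng)
            lp_prop = logpost_fn(prop)
            log_alpha = lp_prop - lp + (corr if hastings_correction else 0.0)
            alpha = math.exp(min(0.0, log_alpha))
            if rng.random() < alpha:
                x, lp = prop, lp_prop
            log_scales = np.clip(
                log_scales + (alpha - target) / t**0.6, log_lo, log_hi
            )
        else:
            j = (t - 1) % d
            prop, corr = _propose_coord(x, j, math.exp(log_scales[j]), bounds, rng)
            lp_prop = logpost_fn(prop)
            log_alpha = lp_prop - lp + (corr if hastings_correction else 0.0)
            alpha = math.exp(min(0.0, log_alpha))
            if rng.random() < alpha:
                x, lp = prop, lp_prop
            log_scales[j] = min(
                max(log_scales[j] + (alpha - target) / max(t / d, 1.0) ** 0.6,
                    log_lo[j]),
                log_hi[j],
            )
        n_acc += alpha
        win_acc += alpha
        if t % config.adapt_window == 0:
            if abs(win_acc / config.adapt_window - target) <= config.adapt_tol:
                stable += 1
            else:
                stable = 0
            win_acc = 0.0
            if stable >= config.adapt_stable_windows:
                break
    return AdaptResult(np.exp(log_scales), x, lp, n_acc / t, t)


def _init_scales(config: MCMCConfig, bounds: Bounds) -> np.ndarray:
    if config.proposal_scales is not None:
        scales = np.asarray(config.proposal_scales, dtype=float).copy()
        if len(scales) != bounds.dim or (scales <= 0).any():
            raise ValueError("proposal_scales must be positive, one per parameter")
        return scales
    return (bounds.upper - bounds.lower) / 20.0


# ---------------------------------------------------------------------------
# The three-phase sampler
# ---------------------------------------------------------------------------

def run_mcmc(
    logpost_fn: Callable[[np.ndarray], float],
    init: np.ndarray,
    bounds: Bounds,
    config: MCMCConfig | None = None,
    param_names: Sequence[str] | None = None,
    two_condition: bool = False,
    hastings_correction: bool = True,
) -> Chain:
    """Adapt, burn in, then sample; fully reproducible under ``config.seed``.

    ``hastings_correction=False`` disables the truncated-proposal correction
    (for regression tests of the correction only; it biases the chain near
    bounds and must never be used for inference).
    """
    config = config or MCMCConfig()
    init = np.asarray(init, dtype=float)
    rng = np.random.default_rng(config.seed)
    mult = config.two_condition_multiplier if two_condition else 1

    adapt = adapt_scales(
        logpost_fn,
        init,
        bounds,
        config,
        rng,
        max_iters=config.adapt_max_iters * mult,
        hastings_correction=hastings_correction,
    )
    scales = adapt.scales
    x, lp = adapt.state.copy(), adapt.logpost

    d = bounds.dim
    per_coord = config.update_mode == "per_coordinate"
    n_burn = config.burnin_iters * mult
    n_samp = config.sample_iters * mult
    n_keep = n_samp // config.thin
    draws = np.empty((n_keep, d))
    logposts = np.empty(n_keep)
    n_acc = 0
    consec_rej = 0
    max_consec_rej = 0

    kept = 0
    for t in range(n_burn + n_samp):
        if per_coord:
            j = t % d
            prop, corr = _propose_coord(x, j, scales[j], bounds, rng)
        else:
            prop, corr = propose_truncated(x, scales, bounds, rng)
        lp_prop = logpost_fn(prop)
        log_alpha = lp_prop - lp + (corr if hastings_correction else 0.0)
        if log_alpha >= 0.0 or rng.random() < math.exp(log_alpha):
            x, lp = prop, lp_prop
            if t >= n_burn:
                n_acc += 1
            consec_rej = 0
        else:
            consec_rej += 1
            max_consec_rej = max(max_consec_rej, consec_rej)
        if t >= n_burn and (t - n_burn + 1) % config.thin == 0 and kept < n_keep:
            draws[kept] = x
            logposts[kept] = lp
            kept += 1

    diagnostics = {
        "adapt_iters": adapt.n_iters,
        "adapt_acceptance": adapt.acceptance_rate,
        "max_consecutive_rejections": max_consec_rej,
        "stuck": max_consec_rej >= 10_000,
    }
    if diagnostics["stuck"]:
        warnings.warn(
            "chain rejected 10,000+ consecutive proposals; posterior may be "
            "degenerate or scales mistuned",
            RuntimeWarning,
        )
    diagnostics["autocorr_time"] = np.array(
        [autocorr_time(draws[:, i]) for i in range(d)]
    )
    names = tuple(param_names) if param_names else tuple(f"p{i}" for i in range(d))
    return Chain(
        draws=draws,
        logposts=logposts,
        acceptance_rate=n_acc / max(n_samp, 1),
        tuned_scales=scales,
        bounds=bounds,
        param_names=names,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def shortest_interval(samples, mass: float = 0.9) -> tuple[float, float]:
    """Shortest interval containing at least ``mass`` of the draws.

    Among all contiguous windows of ceil(mass*N) order statistics, the
    narrowest wins; ties go to the lowest start.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 20:
        raise ValueError("need at least 20 samples for a credible interval")
    m = int(math.ceil(mass * n))
    if m > n:
        raise ValueError("window larger than sample")
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest-start) tie
    return float(s[i]), float(s[i + m - 1])


def autocorr_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time with an automatic (Sokal) window:
    the smallest M with M >= c * tau(M).  Returns nan for a constant chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    if n < 2 or np.allclose(x, 0.0):
        return float("nan")
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    acf /= acf[0]
    taus = 2.0 * np.cumsum(acf) - 1.0
    window = np.arange(n) >= c * taus
    idx = np.argmax(window) if window.any() else n - 1
    return float(max(taus[idx], 1.0))


def summarize(chain: Chain, mass: float = 0.9) -> PosteriorSummary:
    """Per-parameter posterior mean, shortest CrI, mode and autocorrelation
    time.  Constant (degenerate) parameters are flagged and get a zero-width
    interval."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    d = chain.draws.shape[1]
    mean = chain.draws.mean(axis=0)
    lo = np.empty(d)
    hi = np.empty(d)
    tau = np.empty(d)
    degen = np.zeros(d, dtype=bool)
    for i in range(d):
        col = chain.draws[:, i]
        if np.allclose(col, col[0]):
            lo[i] = hi[i] = col[0]
            tau[i] = float("nan")
            degen[i] = True
        else:
            lo[i], hi[i] = shortest_interval(col, mass)
            tau[i] = autocorr_time(col)
    mode = chain.draws[int(np.argmax(chain.logposts))].copy()
    return PosteriorSummary(chain.param_names, mean, lo, hi, mode, tau, degen, mass)


# ---------------------------------------------------------------------------
# Model log-likelihood evaluators and high-level fits
# ---------------------------------------------------------------------------

def _precompute_groups(data: Dataset):
    """Per (pool size) group: (k, log2 of detects, number of non-detects)."""
    groups = []
    for k in sorted(set(data.k.tolist())):
        sub = data.values[data.k == k]
        detects = sub[sub > 0]
        groups.append((int(k), np.log2(detects), int((sub == 0).sum())))
    return groups


def _group_loglik(k, z, n0, pi, mu, sigma, c, m):
    total = 0.0
    if k == 1:
        if z.size:
            if pi <= 0.0:
                return -np.inf
            total += z.size * math.log(pi)
            total += float(
                np.sum(
                    -0.5 * ((z - mu) / sigma) ** 2
                    - math.log(sigma)
                    - _LOG_SQRT_2PI
                    - z * LN2
                    - math.log(LN2)
                )
            )
            total += float(np.sum(_log_expit((z - c) / m)))
        if n0:
            p0 = (1.0 - pi) + pi * _survive(mu, sigma, c, m)
            total += n0 * math.log(p0) if p0 > 0 else -np.inf
        return total
    ls = np.arange(1, k + 1)
    if pi <= 0.0:
        return -np.inf if z.size else 0.0
    logw = _binom_logpmf(ls, k, pi)
    se2 = (sigma * LN2) ** 2
    sl_e2 = np.log(np.expm1(se2) / ls + 1.0)
    ml = (np.log(ls) + mu * LN2 + (se2 - sl_e2) / 2.0) / LN2
    sl = np.sqrt(sl_e2) / LN2
    if z.size:
        comp = (
            -0.5 * ((z[:, None] - ml) / sl) ** 2
            - np.log(sl)
            - _LOG_SQRT_2PI
            - z[:, None] * LN2
            - math.log(LN2)
        )
        total += float(np.sum(logsumexp(comp + logw, axis=1)))
        total += float(np.sum(_log_expit((z - c) / m)))
    if n0:
        surv = np.array([_survive(ml[j], sl[j], c, m) for j in range(k)])
        p0 = (1.0 - pi) ** k + float(np.dot(np.exp(logw), surv))
        total += n0 * math.log(p0) if p0 > 0 else -np.inf
    return total


def make_loglik(data: Dataset, two_condition: bool = False):
    """Build a fast log-likelihood evaluator theta -> float for MCMC.

    Single-condition theta is (pi, mu, sigma, c, m); two-condition theta is
    (pi_a, mu_a, sigma_a, pi_b, mu_b, sigma_b, c, m) with shared detection.
    Numerically identical to the reference likelihoods in ``hetmix.model``.
    """
    if two_condition:
        conds = data.conditions()
        if len(conds) != 2:
            raise ValueError(f"expected exactly two conditions, got {conds}")
        groups_a = _precompute_groups(data.select(condition=conds[0]))
        groups_b = _precompute_groups(data.select(condition=conds[1]))

        def loglik(theta):
            pa, ma_, sa, pb, mb_, sb, c, m = theta
            total = 0.0
            for k, z, n0 in groups_a:
                total += _group_loglik(k, z, n0, pa, ma_, sa, c, m)
                if total == -np.inf:
                    return total
            for k, z, n0 in groups_b:
                total += _group_loglik(k, z, n0, pb, mb_, sb, c, m)
                if total == -np.inf:
                    return total
            return total

        return loglik

    if len(set(data.condition)) != 1:
        raise ValueError("single-condition likelihood expects one condition")
    groups = _precompute_groups(data)

    def loglik(theta):
        pi, mu, sigma, c, m = theta
        total = 0.0
        for k, z, n0 in groups:
            total += _group_loglik(k, z, n0, pi, mu, sigma, c, m)
            if total == -np.inf:
                return total
        return total

    return loglik


def moment_init(data: Dataset) -> np.ndarray:
    """Moment-style start for (pi, mu, sigma, c, m).

    pi starts at the observed single-cell detect fraction (clipped to
    [0.05, 0.95]); mu and sigma at the mean/SD of observed positive log2
    values; c at their 10th percentile; m at 1.
    """
    singles = data.values[data.k == 1]
    if singles.size:
        frac = float((singles > 0).mean())
    else:
        # no single cells: invert the k-cell all-OFF rate
        k = int(data.k.min())
        zero_rate = float((data.values == 0).mean())
        frac = 1.0 - min(max(zero_rate, 1e-6), 1.0 - 1e-6) ** (1.0 / k)
    pi0 = min(max(frac, 0.05), 0.95)
    pos = data.values[data.values > 0]
    if pos.size == 0:
        return np.array([pi0, 20.0, 2.0, 20.0, 1.0])
    z = np.log2(pos)
    mu0 = min(max(float(z.mean()), 0.0), 40.0)
    sd = float(z.std(ddof=1)) if z.size > 1 else 1.0
    sigma0 = min(max(sd, 0.1), 5.0)
    c0 = min(max(float(np.percentile(z, 10)), 0.0), 40.0)
    return np.array([pi0, mu0, sigma0, c0, 1.0])


def fit_single_condition(
    data: Dataset,
    config: MCMCConfig | None = None,
    bounds: Bounds | None = None,
    logprior: Callable[[np.ndarray], float] | None = None,
) -> Chain:
    """Fit the five-parameter model to one gene-condition dataset."""
    config = config or MCMCConfig()
    bounds = bounds or Bounds.single_condition()
    loglik = make_loglik(data)
    logpost = loglik if logprior is None else (lambda th: loglik(th) + logprior(th))
    init = np.clip(moment_init(data), bounds.lower, bounds.upper)
    return run_mcmc(logpost, init, bounds, config, param_names=SINGLE_PARAM_NAMES)


def fit_two_condition(
    data: Dataset,
    config: MCMCConfig | None = None,
    bounds: Bounds | None = None,
    logprior: Callable[[np.ndarray], float] | None = None,
) -> Chain:
    """Fit the eight-parameter two-condition model (shared detection);
    phase lengths are doubled relative to the single-condition defaults."""
    config = config or MCMCConfig()
    bounds = bounds or Bounds.two_condition()
    conds = data.conditions()
    loglik = make_loglik(data, two_condition=True)
    logpost = loglik if logprior is None else (lambda th: loglik(th) + logprior(th))
    ia = moment_init(data.select(condition=conds[0]))
    ib = moment_init(data.select(condition=conds[1]))
    det0 = (ia[3:] + ib[3:]) / 2.0
    init = np.concatenate([ia[:3], ib[:3], det0])
    init = np.clip(init, bounds.lower, bounds.upper)
    return run_mcmc(
        logpost,
        init,
        bounds,
        config,
        param_names=TWO_CONDITION_PARAM_NAMES,
        two_condition=True,
    )
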
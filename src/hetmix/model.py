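"""Probabilistic model of single- and k-cell gene expression with mis-detection.

The true expression G of a gene in a random cell is a zero-inflated
log-normal: a cell is ON with probability ``pi`` and then expresses at a
level X with ``log2 X ~ Normal(mu, sigma)``; OFF cells express nothing.
Any true amount g is *detected* by the assay with logistic probability
``DP(g) = 1 / (1 + exp(-(log2 g - c) / m))``; non-detects are reported as 0.
A k-cell sample pools the transcripts of k independent cells before the same
detection step, so its positive part is a binomial mixture over the number of
ON cells in the pool, each component being a sum of i.i.d. log-normals that we
approximate by a moment-matched log-normal (Fenton-Wilkinson).

Measurements live on the linear scale ``2**Et`` with Et = 40 - Ct; a value of
exactly 0 encodes a non-detect.  All continuous densities are taken with
respect to the linear measurement scale (the log2 change-of-variable Jacobian
``1/(x ln 2)`` is included), so the point mass at zero plus the continuous
part integrate to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
from scipy.special import expit, gammaln, logsumexp, ndtr

LN2 = math.log(2.0)
_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# Gauss-Hermite rule used for E[f(Z)] with Z Gaussian in log2 space.
GH_NODES, GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)
_GH_WNORM = GH_WEIGHTS / math.sqrt(math.pi)

# Gauss-Legendre rule for the steep-logistic branch of the non-detect
# integral: the exponentially localized difference between the logistic and
# its step limit, integrated on u = (z - c)/m over |u| <= 45.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(48)
_GL_U = np.concatenate([22.5 * (_GL_X + 1.0), -22.5 * (_GL_X + 1.0)])
_GL_WU = np.concatenate([22.5 * _GL_W, 22.5 * _GL_W])
_GL_G = np.where(_GL_U > 0, expit(-_GL_U), -expit(_GL_U))

__all__ = [
    "LN2",
    "CHParams",
    "DetectionParams",
    "GeneModel",
    "TwoConditionModel",
    "FWParams",
    "Dataset",
    "detection_prob",
    "on_cell_logdensity",
    "fw_params",
    "nondetect_on_prob",
    "sc_loglik",
    "kc_loglik",
    "kc_loglik_empirical",
    "joint_loglik",
    "two_condition_loglik",
    "log_mean_expression",
    "on_fraction_entropy",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CHParams:
    """Cellular heterogeneity parameters of one condition.

    pi
        Fraction of ON cells (probability).
    mu
        Mean of log2 expression among ON cells, in Et units.
    sigma
        Standard deviation of log2 expression among ON cells, in Et units.
    """

    pi: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if not 0.0 <= self.mu <= 40.0:
            raise ValueError(f"mu must be in [0, 40] Et, got {self.mu}")
        if not 0.0 <= self.sigma <= 40.0:
            raise ValueError(f"sigma must be in [0, 40] Et, got {self.sigma}")


@dataclass(frozen=True)
class DetectionParams:
    """Logistic detection ('assay') parameters, shared across conditions.

    c
        Intercept: Et level at which detection probability is 50%.
    m
        Slope scale in Et units per logit; smaller m = steeper detection.
    """

    c: float
    m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 40.0:
            raise ValueError(f"c must be in [0, 40] Et, got {self.c}")
        if not 0.0 < self.m <= 5.0:
            raise ValueError(f"m must be in (0, 5], got {self.m}")


@dataclass(frozen=True)
class GeneModel:
    """The five single-condition parameters: (pi, mu, sigma) plus (c, m)."""

    ch: CHParams
    det: DetectionParams


@dataclass(frozen=True)
class TwoConditionModel:
    """Eight-parameter model: condition-specific CHPs, shared detection."""

    ch_a: CHParams
    ch_b: CHParams
    det: DetectionParams


@dataclass(frozen=True)
class FWParams:
    """Log2-space parameters of the log-normal approximating a sum of l
    i.i.d. ON-cell expression levels (Fenton-Wilkinson moment matching)."""

    mu_l: float
    sigma_l: float


@dataclass
class Dataset:
    """Observed measurements of one gene.

    values
        Linear-scale measurements (``2**Et``); exactly 0 encodes non-detect.
    k
        Cells pooled per sample (1 for single cells).
    condition
        Condition label per sample.
    plate
        Optional plate label per sample.
    """

    gene_id: str
    values: np.ndarray
    k: np.ndarray
    condition: np.ndarray
    plate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.k = np.asarray(self.k, dtype=int)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not (self.values >= 0).all():
            raise ValueError("values must be >= 0 (0 encodes non-detect)")
        if not (self.k >= 1).all():
            raise ValueError("pool sizes k must be >= 1")
        if len(self.k) != len(self.values) or len(self.condition) != len(self.values):
            raise ValueError("values, k and condition must have equal length")
        if self.plate is not None:
            self.plate = np.asarray(self.plate, dtype=object)
            if len(self.plate) != len(self.values):
                raise ValueError("plate must match values in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def detected(self) -> np.ndarray:
        return self.values > 0

    @property
    def et(self) -> np.ndarray:
        """Et values; non-detects map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.values)

    def conditions(self) -> list:
        seen: list = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen

    def select(self, condition=None, k=None) -> "Dataset":
        mask = np.ones(len(self), dtype=bool)
        if condition is not None:
            mask &= self.condition == condition
        if k is not None:
            mask &= self.k == k
        return Dataset(
            self.gene_id,
            self.values[mask],
            self.k[mask],
            self.condition[mask],
            None if self.plate is None else self.plate[mask],
        )

    def n_on_single(self) -> int:
        """Number of detected (positive) single-cell measurements."""
        return int(((self.k == 1) & (self.values > 0)).sum())


# ---------------------------------------------------------------------------
# Elementary densities
# ---------------------------------------------------------------------------

def detection_prob(g, det: DetectionParams):
    """Probability that true linear expression ``g`` is detected.

    Logistic in log2(g) with intercept ``c`` and slope scale ``m``; exactly 0
    at g = 0 (the log2 -> -inf limit: an empty sample is never detected).
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("expression values must be >= 0")
    out = np.zeros_like(g)
    pos = g > 0
    out[pos] = expit((np.log2(g[pos]) - det.c) / det.m)
    if out.ndim == 0:
        return float(out)
    return out


def on_cell_logdensity(x, ch: CHParams):
    """Log density of ON-cell expression X at linear value x.

    Base-2 log-normal: normal density of log2(x) with mean ``mu`` and sd
    ``sigma``, divided by the Jacobian ``x ln 2`` so the density is with
    respect to the linear scale and integrates to one over (0, inf).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be > 0 for the continuous ON-cell density")
    if ch.sigma <= 0:
        raise ValueError("sigma must be > 0 (degenerate distribution)")
    z = np.log2(x)
    out = _normal_logdensity_linear(z, ch.mu, ch.sigma)
    if out.ndim == 0:
        return float(out)
    return out


def _normal_logdensity_linear(z, mu: float, sigma: float):
    """log density at x = 2**z of a base-2 log-normal, given z = log2 x."""
    z = np.asarray(z, dtype=float)
    return (
        -0.5 * ((z - mu) / sigma) ** 2
        - math.log(sigma)
        - _LOG_SQRT_2PI
        - z * LN2
        - math.log(LN2)
    )


def fw_params(l: int, ch: CHParams) -> FWParams:
    """Fenton-Wilkinson log-normal approximation to a sum of ``l`` ON cells.

    Moment matching is done in natural-log space (sigma_e = sigma*ln2) and
    converted back to log2/Et units, so the first two moments of the
    approximating log-normal equal those of the sum of l i.i.d. copies of X.
    """
    if l < 1:
        raise ValueError("l must be a positive integer")
    if ch.sigma == 0.0:
        # sum of l identical constants: 2**(mu + log2 l)
        return FWParams(ch.mu + math.log2(l), 0.0)
    se2 = (ch.sigma * LN2) ** 2
    sl_e2 = math.log(math.expm1(se2) / l + 1.0)
    ml_e = math.log(l) + ch.mu * LN2 + (se2 - sl_e2) / 2.0
    return FWParams(ml_e / LN2, math.sqrt(sl_e2) / LN2)


def nondetect_on_prob(mu: float, sigma: float, det: DetectionParams) -> float:
    """E[1 - DP(X)] for X base-2 log-normal with parameters (mu, sigma).

    The probability that an expressing sample escapes detection: the
    non-detect integral of the likelihood displays.  Deterministic
    quadrature, accurate to ~1e-12 in every regime: 64-node Gauss-Hermite
    over the exactly-Gaussian log2 scale when the logistic transition is
    wide (m >= sigma), otherwise the exact step-limit Phi((c - mu)/sigma)
    plus a Gauss-Legendre integral of the exponentially localized
    logistic-minus-step correction.  sigma = 0 is the degenerate
    point-mass limit.
    """
    return _survive(mu, sigma, det.c, det.m)


def _survive(mu: float, sigma: float, c: float, m: float) -> float:
    if sigma == 0.0:
        return float(expit((c - mu) / m))
    if m >= sigma:
        z = mu + _SQRT2 * sigma * GH_NODES
        return float(np.dot(_GH_WNORM, expit((c - z) / m)))
    base = float(ndtr((c - mu) / sigma))
    z = c + m * _GL_U
    phi = np.exp(-0.5 * ((z - mu) / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    corr = m * float(np.dot(_GL_WU * _GL_G, phi))
    return min(max(base + corr, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def _check_single_condition(data: Dataset) -> None:
    if len(data) == 0:
        raise ValueError("empty dataset")
    if len(set(data.condition)) != 1:
        raise ValueError("likelihood expects a single-condition dataset")


def sc_loglik(data: Dataset, model: GeneModel) -> float:
    """Log-likelihood of the five parameters given single-cell measurements.

    A detect h > 0 contributes ``pi * P(X = h) * DP(h)``; a non-detect
    contributes ``(1 - pi) + pi * E[1 - DP(X)]`` (OFF cell, or ON cell whose
    expression escaped detection).
    """
    _check_single_condition(data)
    if not (data.k == 1).all():
        raise ValueError("sc_loglik requires k = 1 for every sample")
    ch, det = model.ch, model.det
    detects = data.values[data.values > 0]
    n0 = int((data.values == 0).sum())
    total = 0.0
    if detects.size:
        if ch.pi == 0.0:
            return -np.inf
        if ch.sigma <= 0:
            raise ValueError("sigma must be > 0 to evaluate detects")
        z = np.log2(detects)
        logdens = _normal_logdensity_linear(z, ch.mu, ch.sigma)
        logdp = _log_expit((z - det.c) / det.m)
        total += detects.size * math.log(ch.pi) + float(logdens.sum() + logdp.sum())
    if n0:
        p0 = (1.0 - ch.pi) + ch.pi * nondetect_on_prob(ch.mu, ch.sigma, det)
        total += n0 * _safe_log(p0)
    return total


def _log_expit(x):
    # log(1/(1+e^-x)) = -log1p(e^-x), stable both tails
    x = np.asarray(x, dtype=float)
    return -np.logaddexp(0.0, -x)


def _safe_log(p: float) -> float:
    return math.log(p) if p > 0 else -np.inf


def _binom_logpmf(l: np.ndarray, k: int, pi: float) -> np.ndarray:
    l = np.asarray(l, dtype=float)
    if pi == 0.0:
        return np.where(l == 0, 0.0, -np.inf)
    if pi == 1.0:
        return np.where(l == k, 0.0, -np.inf)
    return (
        gammaln(k + 1)
        - gammaln(l + 1)
        - gammaln(k - l + 1)
        + l * math.log(pi)
        + (k - l) * math.log1p(-pi)
    )


def kc_loglik(data: Dataset, model: GeneModel) -> float:
    """Log-likelihood given k-cell pooled measurements (common pool size k).

    The positive part is a Binomial(k, pi) mixture over the number l of ON
    cells in the pool, each component a Fenton-Wilkinson log-normal; a
    non-detect is either all-OFF, ``(1-pi)**k``, or an expressing pool that
    escaped detection.  For k = 1 this reproduces ``sc_loglik`` exactly.
    """
    _check_single_condition(data)
    kvals = set(data.k.tolist())
    if len(kvals) != 1:
        raise ValueError("kc_loglik requires a single common pool size k")
    k = kvals.pop()
    ch, det = model.ch, model.det
    detects = data.values[data.values > 0]
    n0 = int((data.values == 0).sum())

    ls = np.arange(1, k + 1)
    if ch.pi == 0.0:
        return -np.inf if detects.size else 0.0
    logw = _binom_logpmf(ls, k, ch.pi)
    fw = [fw_params(int(l), ch) for l in ls]

    total = 0.0
    if detects.size:
        if ch.sigma <= 0:
            raise ValueError("sigma must be > 0 to evaluate detects")
        z = np.log2(detects)
        comp = np.empty((detects.size, k))
        for j, p in enumerate(fw):
            comp[:, j] = _normal_logdensity_linear(z, p.mu_l, p.sigma_l)
        mix = logsumexp(comp + logw[None, :], axis=1)
        logdp = _log_expit((z - det.c) / det.m)
        total += float(mix.sum() + logdp.sum())
    if n0:
        surv = np.array([nondetect_on_prob(p.mu_l, p.sigma_l, det) for p in fw])
        p0 = (1.0 - ch.pi) ** k + float(np.dot(np.exp(logw), surv))
        total += n0 * _safe_log(p0)
    return total


def kc_loglik_empirical(
    data: Dataset,
    model: GeneModel,
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo/KDE alternative to the analytic k-cell likelihood.

    Draws ``n_draws`` simulated k-cell measurements from the generative model
    (k single cells summed, then the logistic detection coin), fits a
    Gaussian KDE (Silverman bandwidth) to the Et values of the positive
    draws, and reads the likelihood of each observed measurement off the KDE;
    non-detects use the empirical non-detect fraction.
    """
    from scipy.stats import gaussian_kde

    _check_single_condition(data)
    kvals = set(data.k.tolist())
    if len(kvals) != 1:
        raise ValueError("kc_loglik_empirical requires a common pool size k")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a usable KDE")
    k = kvals.pop()
    rng = np.random.default_rng(rng)
    ch, det = model.ch, model.det

    n_on = rng.binomial(k, ch.pi, size=n_draws)
    v = np.zeros(n_draws)
    pos = n_on > 0
    if pos.any():
        counts = n_on[pos]
        singles = np.exp2(rng.normal(ch.mu, ch.sigma, size=int(counts.sum())))
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        v[pos] = np.add.reduceat(singles, starts)
    detected = np.zeros(n_draws, dtype=bool)
    if pos.any():
        dp = detection_prob(v[pos], det)
        detected[pos] = rng.random(pos.sum()) < dp
    w = np.where(detected, v, 0.0)

    obs = data.values
    p_pos = detected.mean()
    total = 0.0
    n0 = int((obs == 0).sum())
    detects = obs[obs > 0]
    if detects.size:
        if not detected.any():
            warnings.warn(
                "all simulated draws were non-detects but data contains "
                "detects; empirical likelihood is -inf",
                RuntimeWarning,
            )
            return -np.inf
        kde = gaussian_kde(np.log2(w[detected]), bw_method="silverman")
        dens = np.maximum(kde(np.log2(detects)), 1e-300)
        # KDE is in Et space; convert to linear-scale density.
        total += float(
            np.log(p_pos) * detects.size
            + np.sum(np.log(dens) - np.log(detects * LN2))
        )
    if n0:
        total += n0 * _safe_log(max(1.0 - p_pos, 1e-300))
    return total


def joint_loglik(data: Dataset, model: GeneModel) -> float:
    """Log-likelihood of mixed single-/k-cell data: the sum over k-groups."""
    _check_single_condition(data)
    total = 0.0
    for k in sorted(set(data.k.tolist())):
        sub = data.select(k=k)
        if k == 1:
            total += sc_loglik(sub, model)
        else:
            total += kc_loglik(sub, model)
    return total


def two_condition_loglik(data: Dataset, model: TwoConditionModel) -> float:
    """Log-likelihood of the eight-parameter two-condition model.

    Conditions share the detection parameters (same assay) but have their
    own CHPs; the log-likelihoods of the two conditions simply add.
    """
    conds = data.conditions()
    if len(conds) != 2:
        raise ValueError(f"expected exactly two conditions, got {conds}")
    la = joint_loglik(data.select(condition=conds[0]), GeneModel(model.ch_a, model.det))
    lb = joint_loglik(data.select(condition=conds[1]), GeneModel(model.ch_b, model.det))
    return la + lb


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def log_mean_expression(ch: CHParams) -> float:
    """log2 of the population-average expression E(G).

    log2 E(G) = log2 pi + mu + sigma^2 ln(2)/2; -inf when pi = 0.
    """
    if ch.pi == 0.0:
        return -np.inf
    return math.log2(ch.pi) + ch.mu + ch.sigma**2 * LN2 / 2.0


def on_fraction_entropy(pi: float) -> float:
    """Shannon entropy (bits) of the ON/OFF split: a population with a
    balanced mix of ON and OFF cells is maximally (discretely) heterogeneous."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must be in [0, 1]")
    if pi in (0.0, 1.0):
        return 0.0
    return float(-pi * math.log2(pi) - (1.0 - pi) * math.log2(1.0 - pi))
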
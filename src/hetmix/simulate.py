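"""Generative engine: simulate single-/k-cell data under the model.

Implements the generative equations behind the likelihood (ON/OFF Bernoulli,
base-2 log-normal ON expression, logistic detection, optional additive
Gaussian Et-space measurement noise on detects) and the scenario presets used
in the simulation benchmarks: three inference-difficulty levels, three assay
sensitivities defined relative to (mu, sigma), five measurement-noise
configurations, and single- or two-condition designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CHParams,
    Dataset,
    DetectionParams,
    GeneModel,
    detection_prob,
    nondetect_on_prob,
)

__all__ = [
    "NoiseConfig",
    "ScenarioSpec",
    "DIFFICULTY_PRESETS",
    "SENSITIVITY_PRESETS",
    "NOISE_PRESETS",
    "TWO_CONDITION_PI_PAIRS",
    "sim_true_singles",
    "sim_true_kcells",
    "apply_detection",
    "add_measurement_noise",
    "simulate_dataset",
    "make_scenario",
    "make_two_condition_scenario",
    "mean_on_detection_rate",
]

# Difficulty presets: (pi, sigma); mu = 10 Et in all scenarios.
DIFFICULTY_PRESETS = {
    "low": (0.8, 0.5),
    "medium": (0.5, 1.0),
    "high": (0.2, 2.0),
}
SCENARIO_MU = 10.0

# Assay sensitivity presets: c as an offset from mu in units of sigma;
# m = sigma/4 throughout.  They detect ~82% / 50% / ~18% of ON cells.
SENSITIVITY_PRESETS = {"good": -1.0, "medium": 0.0, "bad": +1.0}

TWO_CONDITION_PI_PAIRS = [(0.8, 0.5), (0.6, 0.4), (0.5, 0.2)]

# Floor (Et) keeping noisy detects strictly positive: noise never converts
# a detect into a non-detect.
NOISE_ET_FLOOR = 0.01


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian white noise in Et space applied to detects only."""

    kind: str = "none"  # none | constant | two_step
    sd_single: float = 0.0
    sd_kcell: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "constant", "two_step"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd_single < 0 or self.sd_kcell < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.kind == "constant" and self.sd_single != self.sd_kcell:
            raise ValueError("constant noise requires sd_single == sd_kcell")
        if self.kind == "none" and (self.sd_single or self.sd_kcell):
            raise ValueError("kind='none' implies zero standard deviations")


NOISE_PRESETS = {
    "none": NoiseConfig("none", 0.0, 0.0),
    "C0.5": NoiseConfig("constant", 0.5, 0.5),
    "C1": NoiseConfig("constant", 1.0, 1.0),
    "T0.5,0.25": NoiseConfig("two_step", 0.5, 0.25),
    "T1,0.5": NoiseConfig("two_step", 1.0, 0.5),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation recipe: difficulty x sensitivity x noise x k x n x mode."""

    difficulty: str = "low"
    sensitivity: str = "good"
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    k: int = 10
    n: int = 1000
    mode: str = "SCKC"  # SC | KC | SCKC
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.difficulty not in DIFFICULTY_PRESETS:
            raise ValueError(f"unknown difficulty {self.difficulty!r}")
        if self.sensitivity not in SENSITIVITY_PRESETS:
            raise ValueError(f"unknown sensitivity {self.sensitivity!r}")
        if self.mode not in ("SC", "KC", "SCKC"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k < 1 or self.n < 1:
            raise ValueError("k and n must be >= 1")

    def resolve(self) -> GeneModel:
        """The true GeneModel this scenario simulates from."""
        pi, sigma = DIFFICULTY_PRESETS[self.difficulty]
        ch = CHParams(pi, SCENARIO_MU, sigma)
        return GeneModel(ch, sensitivity_detection(ch, self.sensitivity))


def sensitivity_detection(ch: CHParams, sensitivity: str) -> DetectionParams:
    """Detection parameters of a named assay-sensitivity preset, relative to
    the ON-cell distribution: c = mu + offset*sigma, m = sigma/4."""
    off = SENSITIVITY_PRESETS[sensitivity]
    return DetectionParams(ch.mu + off * ch.sigma, ch.sigma / 4.0)


# ---------------------------------------------------------------------------
# Generative primitives
# ---------------------------------------------------------------------------

def sim_true_singles(n: int, ch: CHParams, rng: np.random.Generator):
    """True single-cell expression G = I * X on the linear scale.

    Returns (values, latent) with latent['on'] the ON indicators I and
    latent['x'] the ON expression X (only meaningful where on).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    on = rng.random(n) < ch.pi
    x = np.exp2(rng.normal(ch.mu, ch.sigma, size=n))
    values = np.where(on, x, 0.0)
    return values, {"on": on, "x": x}


def sim_true_kcells(n: int, k: int, ch: CHParams, rng: np.random.Generator):
    """True k-cell expression V = sum of k i.i.d. single-cell values.

    Returns (values, latent) with latent['l'] the Binomial(k, pi) number of
    ON cells in each pool.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    l = rng.binomial(k, ch.pi, size=n)
    values = np.zeros(n)
    pos = l > 0
    if pos.any():
        counts = l[pos]
        singles = np.exp2(rng.normal(ch.mu, ch.sigma, size=int(counts.sum())))
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        values[pos] = np.add.reduceat(singles, starts)
    return values, {"l": l}


def apply_detection(values, det: DetectionParams, rng: np.random.Generator):
    """Subject true values to the logistic assay: keep each positive value
    with probability DP(value), else report 0.  Zeros stay zero."""
    values = np.asarray(values, dtype=float)
    dp = detection_prob(values, det)
    keep = rng.random(values.shape) < dp
    return np.where(keep, values, 0.0)


def add_measurement_noise(
    values,
    is_kcell: bool,
    noise: NoiseConfig,
    rng: np.random.Generator,
):
    """Add Gaussian Et-space white noise to detects; non-detects untouched.

    Noisy Et values are floored at a small positive value so a detect is
    never converted into a non-detect by measurement noise.
    """
    values = np.asarray(values, dtype=float)
    if noise.kind == "none":
        return values.copy()
    sd = noise.sd_kcell if is_kcell else noise.sd_single
    out = values.copy()
    pos = values > 0
    if sd > 0 and pos.any():
        et = np.log2(values[pos]) + rng.normal(0.0, sd, size=int(pos.sum()))
        out[pos] = np.exp2(np.maximum(et, NOISE_ET_FLOOR))
    return out


# ---------------------------------------------------------------------------
# Dataset-level simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    model: GeneModel,
    n_single: int,
    n_kcell: int,
    k: int,
    rng: np.random.Generator,
    noise: NoiseConfig | None = None,
    condition: str = "A",
    gene_id: str = "sim",
    return_latent: bool = False,
):
    """Simulate one gene-condition dataset with the given sample structure."""
    noise = noise or NoiseConfig()
    vals, ks, latents = [], [], {}
    if n_single:
        g, lat = sim_true_singles(n_single, model.ch, rng)
        h = apply_detection(g, model.det, rng)
        h = add_measurement_noise(h, False, noise, rng)
        vals.append(h)
        ks.append(np.ones(n_single, dtype=int))
        latents["single"] = {"true": g, **lat}
    if n_kcell:
        v, lat = sim_true_kcells(n_kcell, k, model.ch, rng)
        w = apply_detection(v, model.det, rng)
        w = add_measurement_noise(w, True, noise, rng)
        vals.append(w)
        ks.append(np.full(n_kcell, k, dtype=int))
        latents["kcell"] = {"true": v, **lat}
    if not vals:
        raise ValueError("need at least one sample")
    values = np.concatenate(vals)
    kk = np.concatenate(ks)
    data = Dataset(gene_id, values, kk, np.full(len(values), condition, dtype=object))
    if return_latent:
        return data, latents
    return data


def _mode_split(mode: str, n: int, k: int) -> tuple[int, int]:
    if mode == "SC":
        return n, 0
    if mode == "KC":
        return 0, n
    return n // 2, n - n // 2


def make_scenario(spec: ScenarioSpec, return_latent: bool = False):
    """Simulate a dataset for one scenario preset (single condition)."""
    model = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    n_single, n_kcell = _mode_split(spec.mode, spec.n, spec.k)
    return simulate_dataset(
        model,
        n_single,
        n_kcell,
        spec.k,
        rng,
        noise=spec.noise,
        gene_id=f"{spec.difficulty}-{spec.sensitivity}",
        return_latent=return_latent,
    )


def make_two_condition_scenario(
    pi_pair: tuple[float, float],
    n: int = 1000,
    k: int = 10,
    mode: str = "SCKC",
    sensitivity: str = "good",
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    mu: float = SCENARIO_MU,
    sigma: float = 1.0,
    conditions: tuple[str, str] = ("A", "B"),
    gene_id: str = "sim",
) -> Dataset:
    """Two-condition comparative scenario: pi differs, mu and sigma shared
    (mu = 10 Et, sigma = 1 Et by default), one shared assay for both
    conditions (derived from the shared mu, sigma)."""
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    ch_ref = CHParams(pi_pair[0], mu, sigma)
    det = sensitivity_detection(ch_ref, sensitivity)
    parts = []
    for pi, cond in zip(pi_pair, conditions):
        model = GeneModel(CHParams(pi, mu, sigma), det)
        n_single, n_kcell = _mode_split(mode, n, k)
        parts.append(
            simulate_dataset(
                model, n_single, n_kcell, k, rng,
                noise=noise, condition=cond, gene_id=gene_id,
            )
        )
    values = np.concatenate([p.values for p in parts])
    kk = np.concatenate([p.k for p in parts])
    cond = np.concatenate([p.condition for p in parts])
    return Dataset(gene_id, values, kk, cond)


# ---------------------------------------------------------------------------
# Assay characterization
# ---------------------------------------------------------------------------

def mean_on_detection_rate(
    ch: CHParams,
    det: DetectionParams,
    n_mc: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo estimate of E[DP(X)]: the mean detection probability of an
    expressing (ON) cell.  OFF cells are never detectable, so averaging over
    ON cells makes the rate a property of the assay alone (it depends only on
    (c - mu)/sigma and m/sigma, not on pi)."""
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10000")
    rng = np.random.default_rng(rng)
    x = np.exp2(rng.normal(ch.mu, ch.sigma, size=n_mc))
    return float(detection_prob(x, det).mean())


def mean_on_detection_rate_quadrature(ch: CHParams, det: DetectionParams) -> float:
    """Deterministic (quadrature) version of ``mean_on_detection_rate``."""
    return 1.0 - nondetect_on_prob(ch.mu, ch.sigma, det)
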
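"""Model assessment by posterior-predictive checks.

A fitted gene-condition model is trusted only if data simulated from it are
statistically indistinguishable from the observed data.  The default
criterion draws 100 parameter vectors from the posterior, simulates a
matched-size dataset from each, and runs a two-sample Anderson-Darling test
of simulated vs. observed values separately for the single-cell and k-cell
parts; the model passes if more than 75% of the draws reach AD P >= 0.1 on
every data type present, and the posterior mean of sigma does not exceed 5
(extremely high ON-cell variance is treated as a failed fit).  Two
alternatives are provided: a single AD test on all simulated datasets
concatenated (more powerful for genes with few ON cells), and posterior
predictive p-values of chosen summary statistics.  Genes with fewer than 5
observed ON single cells carry too little information and can be filtered
out up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import anderson_ksamp

from .model import CHParams, Dataset, DetectionParams, GeneModel
from .mcmc import Chain
from .simulate import simulate_dataset

__all__ = [
    "AssessmentResult",
    "PrefilterDecision",
    "posterior_predictive_draws",
    "ad_two_sample_p",
    "assess_default",
    "assess_concat",
    "assess_ppp",
    "prefilter_on_cells",
]


@dataclass
class AssessmentResult:
    """Outcome of a posterior-predictive model check."""

    passed: bool
    pass_fraction: float | None
    per_draw_p: dict = field(default_factory=dict)  # data type -> p-values
    reason: str | None = None  # ad_fraction | sigma_cap | too_few_on_cells
    posterior_mean_sigma: float | None = None

    def to_dict(self) -> dict:
        out = {
            "pass": bool(self.passed),
            "pass_fraction": self.pass_fraction,
            "reason": self.reason,
            "posterior_mean_sigma": self.posterior_mean_sigma,
        }
        for dtype, ps in self.per_draw_p.items():
            ps = np.asarray(ps, dtype=float)
            if ps.size:
                out[f"p_{dtype}_quantiles"] = {
                    q: float(np.quantile(ps, q)) for q in (0.1, 0.5, 0.9)
                }
        return out


@dataclass(frozen=True)
class PrefilterDecision:
    keep: bool
    flagged: bool
    n_on_single: int


def _data_shape(data: Dataset):
    """(n_single, n_kcell, k) of the observed dataset."""
    n_single = int((data.k == 1).sum())
    kc = data.k[data.k > 1]
    if kc.size:
        ks = set(kc.tolist())
        if len(ks) > 1:
            raise ValueError("assessment expects a single k-cell pool size")
        k = ks.pop()
        n_kcell = int(kc.size)
    else:
        k, n_kcell = 10, 0
    return n_single, n_kcell, int(k)


def _chain_models(chain: Chain, n_draws: int, rng: np.random.Generator):
    """n_draws GeneModels sampled with replacement from the (thinned) chain.

    The post-burn-in chain is first thinned by equal spacing to at most 1000
    candidate draws to reduce autocorrelation among the sampled models.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    names = chain.param_names
    required = {"pi", "mu", "sigma", "c", "m"}
    if not required.issubset(names):
        raise ValueError(
            "chain must carry single-condition parameters (pi, mu, sigma, c, m); "
            "extract one condition from a two-condition chain first"
        )
    n = len(chain)
    idx = np.unique(np.linspace(0, n - 1, min(n, 1000)).astype(int))
    pool = chain.draws[idx]
    picks = pool[rng.integers(0, len(pool), size=n_draws)]
    col = {p: names.index(p) for p in required}
    models = []
    for row in picks:
        ch = CHParams(
            min(max(row[col["pi"]], 0.0), 1.0),
            row[col["mu"]],
            min(row[col["sigma"]], 40.0),
        )
        det = DetectionParams(row[col["c"]], row[col["m"]])
        models.append(GeneModel(ch, det))
    return models


def condition_subchain(chain: Chain, condition: str) -> Chain:
    """Extract one condition's five-parameter sub-chain from an
    eight-parameter two-condition chain (condition 'a' or 'b')."""
    suffix = f"_{condition}"
    cols = [f"pi{suffix}", f"mu{suffix}", f"sigma{suffix}", "c", "m"]
    idx = [chain.param_names.index(c) for c in cols]
    return Chain(
        draws=chain.draws[:, idx],
        logposts=chain.logposts,
        acceptance_rate=chain.acceptance_rate,
        tuned_scales=chain.tuned_scales[idx],
        bounds=chain.bounds,
        param_names=("pi", "mu", "sigma", "c", "m"),
        diagnostics=dict(chain.diagnostics),
    )


def posterior_predictive_draws(
    chain: Chain,
    data: Dataset,
    n_draws: int = 100,
    rng: np.random.Generator | int | None = None,
) -> list[Dataset]:
    """Simulate ``n_draws`` datasets from posterior-sampled models, each with
    exactly the observed sample structure (n_single, n_kcell, k)."""
    rng = np.random.default_rng(rng)
    n_single, n_kcell, k = _data_shape(data)
    sims = []
    for model in _chain_models(chain, n_draws, rng):
        sims.append(
            simulate_dataset(model, n_single, n_kcell, k, rng, gene_id=data.gene_id)
        )
    return sims


def ad_two_sample_p(sim, obs) -> float:
    """Two-sample Anderson-Darling p-value (ties-adjusted midrank variant).

    Zeros (non-detects) enter as massive ties: the zero fraction is a central
    feature of the model, so it participates in the comparison rather than
    being excluded.
    """
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.size == 0 or obs.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(sim.size, obs.size) < 5:
        warnings.warn("AD test on a sample smaller than 5: low power", RuntimeWarning)
    if np.all(sim == sim[0]) and np.all(obs == obs[0]) and sim[0] == obs[0]:
        return 0.25  # identical constant samples: no evidence against
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*p-value (capped|floored).*")
        try:
            res = anderson_ksamp([sim, obs], variant="midrank")
        except (TypeError, ValueError):  # older scipy
            res = anderson_ksamp([sim, obs], midrank=True)
    return float(res.pvalue)


def _split_types(data: Dataset) -> dict:
    out = {}
    singles = data.values[data.k == 1]
    kcells = data.values[data.k > 1]
    if singles.size:
        out["single"] = singles
    if kcells.size:
        out["kcell"] = kcells
    return out


def assess_default(
    chain: Chain,
    data: Dataset,
    n_draws: int = 100,
    p_min: float = 0.1,
    fraction_threshold: float = 0.75,
    sigma_cap: float = 5.0,
    rng: np.random.Generator | int | None = None,
) -> AssessmentResult:
    """Default multi-AD-test criterion.

    A posterior draw 'passes' only if the AD test reaches ``p_min`` on every
    data type present (single-cell and k-cell compared separately, each at
    matched sample size); the model passes if the passing fraction exceeds
    ``fraction_threshold`` and the posterior mean of sigma is at most
    ``sigma_cap``.
    """
    rng = np.random.default_rng(rng)
    mean_sigma = float(chain.column("sigma").mean())
    obs = _split_types(data)
    sims = posterior_predictive_draws(chain, data, n_draws, rng)
    per_p: dict = {t: [] for t in obs}
    n_pass = 0
    for sim in sims:
        sim_types = _split_types(sim)
        ok = True
        for t, obs_vals in obs.items():
            p = ad_two_sample_p(sim_types[t], obs_vals)
            per_p[t].append(p)
            ok = ok and p >= p_min
        n_pass += ok
    frac = n_pass / n_draws
    if mean_sigma > sigma_cap:
        return AssessmentResult(False, frac, per_p, "sigma_cap", mean_sigma)
    if frac <= fraction_threshold:
        return AssessmentResult(False, frac, per_p, "ad_fraction", mean_sigma)
    return AssessmentResult(True, frac, per_p, None, mean_sigma)


def assess_concat(
    chain: Chain,
    data: Dataset,
    n_draws: int = 100,
    p_min: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> AssessmentResult:
    """Concatenated single-AD variant: all simulated datasets are pooled into
    one and a single AD test per data type decides.  Pooling enlarges the
    simulated sample, which helps genes with very few ON cells."""
    rng = np.random.default_rng(rng)
    obs = _split_types(data)
    sims = posterior_predictive_draws(chain, data, n_draws, rng)
    per_p: dict = {}
    ok = True
    for t, obs_vals in obs.items():
        pooled = np.concatenate([_split_types(s)[t] for s in sims])
        p = ad_two_sample_p(pooled, obs_vals)
        per_p[t] = [p]
        ok = ok and p >= p_min
    return AssessmentResult(ok, None, per_p, None if ok else "ad_fraction",
                            float(chain.column("sigma").mean()))


_STATISTICS = {
    "mean_on": lambda v: float(np.mean(np.log2(v[v > 0]))) if (v > 0).any() else None,
    "var_on": (
        lambda v: float(np.var(np.log2(v[v > 0]), ddof=1)) if (v > 0).sum() > 1 else None
    ),
    "detect_fraction": lambda v: float((v > 0).mean()),
}


def assess_ppp(
    chain: Chain,
    data: Dataset,
    statistic: str = "mean_on",
    n_draws: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Two-sided posterior predictive p-value of a summary statistic,
    computed per data type: ppp = 2 min(P(sim >= obs), P(sim <= obs)).

    Returns {data type: ppp or None}; None marks an undefined statistic
    (e.g. no ON cells observed), which is explicitly not a rejection.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _STATISTICS[statistic]
    rng = np.random.default_rng(rng)
    obs = _split_types(data)
    sims = posterior_predictive_draws(chain, data, n_draws, rng)
    out = {}
    for t, obs_vals in obs.items():
        s_obs = stat(obs_vals)
        if s_obs is None:
            out[t] = None
            continue
        s_sim = np.array(
            [s for s in (stat(_split_types(sim)[t]) for sim in sims) if s is not None]
        )
        if s_sim.size == 0:
            out[t] = None
            continue
        ge = float((s_sim >= s_obs).mean())
        le = float((s_sim <= s_obs).mean())
        out[t] = min(1.0, 2.0 * min(ge, le))
    return out


def prefilter_on_cells(data: Dataset, min_on: int = 5) -> PrefilterDecision:
    """Drop genes with fewer than ``min_on`` detected single cells: so little
    single-cell information makes the CHPs essentially unidentifiable.  When
    the dataset has no single-cell samples at all, the decision is deferred
    (keep, flagged)."""
    if not (data.k == 1).any():
        return PrefilterDecision(keep=True, flagged=True, n_on_single=0)
    n_on = data.n_on_single()
    return PrefilterDecision(keep=n_on >= min_on, flagged=False, n_on_single=n_on)
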
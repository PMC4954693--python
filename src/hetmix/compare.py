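"""Two-condition comparisons: differential expression and heterogeneity.

Any function of the heterogeneity parameters has a posterior distribution of
its between-condition difference, obtained by applying the function to each
joint posterior draw (the shared detection parameters are thereby averaged
over, tied to the same value in both conditions).  The posterior difference
is reduced to a frequentist-style p-value by the half-space construction
with the null proportion set conservatively to 100%: twice the smaller of
the two posterior half-space masses, floored at 1/N so it is never exactly
zero.  P-values across genes are Benjamini-Hochberg adjusted.  DE calls use
the difference of the population-average expression log2 E(G); DE genes are
further classified by which of pi and mu changed significantly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import CHParams
from .mcmc import Chain, shortest_interval

__all__ = [
    "DifferenceResult",
    "DEModeCall",
    "posterior_delta",
    "halfspace_pvalue",
    "bh_adjust",
    "call_de",
    "classify_de_modes",
    "QUANTITIES",
]


@dataclass
class DifferenceResult:
    """Posterior of (condition A - condition B) for one derived quantity."""

    quantity: str
    delta_samples: np.ndarray
    mean_delta: float
    cri_90: tuple[float, float]
    p: float
    adj_p: float | None = None


@dataclass(frozen=True)
class DEModeCall:
    gene: str
    mode: str  # pi_only | mu_only | both | neither


def _fast_quantity(name: str):
    if name in ("pi", "mu", "sigma"):
        return lambda P, M, S: {"pi": P, "mu": M, "sigma": S}[name]
    if name == "log_mean_expression":
        ln2 = np.log(2.0)

        def f(P, M, S):
            with np.errstate(divide="ignore"):
                return np.where(P > 0, np.log2(np.maximum(P, 1e-300)), -np.inf) \
                    + M + S**2 * ln2 / 2.0

        return f
    if name == "entropy":

        def f(P, M, S):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = -P * np.log2(np.maximum(P, 1e-300)) - (1 - P) * np.log2(
                    np.maximum(1 - P, 1e-300)
                )
            return np.where((P <= 0) | (P >= 1), 0.0, t)

        return f
    return None


QUANTITIES = ("pi", "mu", "sigma", "log_mean_expression", "entropy")


def posterior_delta(chain: Chain, fn) -> np.ndarray:
    """Per-draw difference fn(ch_A) - fn(ch_B) over a two-condition chain.

    ``fn`` is either a quantity name from ``QUANTITIES`` or a callable taking
    a CHParams.  Draws where fn diverges (e.g. log2 E(G) at pi = 0) map to
    the signed infinity of the limit so they still count in the correct
    half-space.
    """
    names = chain.param_names
    needed = {"pi_a", "mu_a", "sigma_a", "pi_b", "mu_b", "sigma_b"}
    if not needed.issubset(names):
        raise ValueError("posterior_delta requires an eight-parameter two-condition chain")
    cols = {n: chain.draws[:, names.index(n)] for n in needed}
    if isinstance(fn, str):
        fast = _fast_quantity(fn)
        if fast is None:
            raise ValueError(f"unknown quantity {fn!r}; options: {QUANTITIES}")
        va = fast(cols["pi_a"], cols["mu_a"], cols["sigma_a"])
        vb = fast(cols["pi_b"], cols["mu_b"], cols["sigma_b"])
        with np.errstate(invalid="ignore"):
            delta = va - vb
        # -inf - -inf: both conditions fully OFF; the difference is null
        delta = np.where(np.isnan(delta), 0.0, delta)
        return delta
    out = np.empty(len(chain))
    for i in range(len(chain)):
        a = CHParams(min(max(cols["pi_a"][i], 0), 1), cols["mu_a"][i], cols["sigma_a"][i])
        b = CHParams(min(max(cols["pi_b"][i], 0), 1), cols["mu_b"][i], cols["sigma_b"][i])
        va, vb = fn(a), fn(b)
        d = va - vb
        out[i] = 0.0 if np.isnan(d) else d
    return out


def halfspace_pvalue(delta_samples) -> float:
    """Convert posterior difference draws to a two-sided p-value.

    p = 2 * min(P(delta <= 0), P(delta >= 0)), capped at 1 and floored at
    1/N (the posterior can never rule a difference out entirely from N
    draws).  Rank-based, hence invariant to monotone rescalings of delta.
    """
    d = np.asarray(delta_samples, dtype=float)
    n = d.size
    if n < 100:
        raise ValueError("need at least 100 posterior draws for a p-value")
    le = float((d <= 0).mean())
    ge = float((d >= 0).mean())
    return max(1.0 / n, min(1.0, 2.0 * min(le, ge)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def difference_result(
    chain: Chain, quantity: str, mass: float = 0.9
) -> DifferenceResult:
    """Posterior difference summary of one quantity for one gene."""
    delta = posterior_delta(chain, quantity)
    finite = delta[np.isfinite(delta)]
    mean_d = float(finite.mean()) if finite.size else float("nan")
    if finite.size >= 20:
        cri = shortest_interval(finite, mass)
    else:
        cri = (float("nan"), float("nan"))
    return DifferenceResult(quantity, delta, mean_d, cri, halfspace_pvalue(delta))


def call_de(
    chains: dict[str, Chain],
    alpha: float = 0.05,
    quantity: str = "log_mean_expression",
) -> pd.DataFrame:
    """Differential-expression calls across genes.

    Per gene: posterior difference of log2 E(G) (the posterior log2
    fold-change), half-space p-value, then BH adjustment across all tested
    genes; a gene is called DE at adj_p < alpha.  Returns one row per gene
    with the posterior mean log2FC and its shortest 90% CrI.
    """
    if not chains:
        raise ValueError("need at least one gene chain")
    genes = list(chains)
    results = {g: difference_result(chains[g], quantity) for g in genes}
    adj = bh_adjust([results[g].p for g in genes])
    rows = []
    for g, ap in zip(genes, adj):
        r = results[g]
        r.adj_p = float(ap)
        rows.append(
            {
                "gene": g,
                "quantity": quantity,
                "mean_delta": r.mean_delta,
                "cri_lo": r.cri_90[0],
                "cri_hi": r.cri_90[1],
                "p": r.p,
                "adj_p": r.adj_p,
                "de": bool(ap < alpha),
            }
        )
    return pd.DataFrame(rows)


def classify_de_modes(
    genes: Sequence[str],
    chains: dict[str, Chain],
    alpha: float = 0.05,
) -> list[DEModeCall]:
    """Classify DE genes by which heterogeneity parameter changed:
    only pi (the ON fraction), only mu (the ON-cell mean), both, or neither.
    The pi and mu tests are each BH-adjusted across the given genes."""
    genes = list(genes)
    if not genes:
        return []
    adj = {}
    for q in ("pi", "mu"):
        ps = [halfspace_pvalue(posterior_delta(chains[g], q)) for g in genes]
        adj[q] = bh_adjust(ps)
    calls = []
    for i, g in enumerate(genes):
        sig_pi = adj["pi"][i] < alpha
        sig_mu = adj["mu"][i] < alpha
        mode = (
            "both" if (sig_pi and sig_mu)
            else "pi_only" if sig_pi
            else "mu_only" if sig_mu
            else "neither"
        )
        calls.append(DEModeCall(g, mode))
    return calls
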
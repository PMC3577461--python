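"""MSA-specific significance model for coupling scores.

The scores of all column pairs of one MSA are treated as an iid sample whose
null component follows a two-parameter beta distribution F0.  The null mean
is estimated by the sample mean of all scores; the null variance by the
sample variance of scores of column pairs in which one column has been
randomly shuffled (which destroys any genuine coupling while preserving the
column compositions).  P-values are X = 1 - F0(score).

The fraction gamma of null pairs is estimated from the p-value histogram on a
window [lambda1, lambda2] where the non-null components contribute
negligible mass, and the significance threshold tau is the largest observed
p-value t <= lambda1 for which the estimated false discovery rate

    FDR(t) = gamma * mu * t / #{p <= t}

stays at or below the target (a Storey-Tibshirani-style procedure).  Sites
are ranked by their connectivity degree -- the number of significant pairs
they participate in -- and those at or above the 90th percentile of nonzero
degrees are called significant for that metric.  A site is CMF-significant
when it is significant under either the U or the UD(alpha) metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .msa_io import Alignment
from .metrics import PairScoreTable, score_from_codes

logger = logging.getLogger(__name__)


@dataclass
class BetaNull:
    """A beta-distribution null F0 fitted from a mean and a variance."""

    a: float
    b: float
    mean: float
    variance: float
    metric_name: str = ""

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shape parameters must be positive")
        implied = self.a / (self.a + self.b)
        if abs(implied - self.mean) > 1e-9:
            raise ValueError("shape parameters inconsistent with stored mean")

    def sf(self, x) -> np.ndarray:
        return stats.beta.sf(x, self.a, self.b)


@dataclass
class SignificanceResult:
    """Everything the significance scan produces for one metric on one MSA."""

    metric_name: str
    pairs: list  # unordered (i, j), filtered-column indices
    scores: np.ndarray
    pvalues: np.ndarray
    null: BetaNull
    gamma_hat: float
    tau: float
    fdr_hat_at_tau: float
    significant_pairs: set
    connectivity: dict  # site -> degree (every retained column present)
    degree_threshold: Optional[float]
    significant_sites: set
    lambda1: float
    lambda2: float
    nu: int
    seed: int
    n_columns: int = 0


def estimate_null_moments(
    msa: Alignment,
    scores: PairScoreTable,
    nu: int = 1000,
    subinterval=(0.2, 0.8),
    seed: int = 0,
    dcm=None,
    alpha: float = 1.0,
):
    """Estimate the null (mean, variance) for the metric of ``scores``.

    The mean is the sample mean of all pair scores.  For the variance, up to
    ``nu`` pairs whose score lies in ``subinterval`` are drawn (all pairs are
    used as candidates when the subinterval is empty, and all candidates are
    used when fewer than ``nu`` qualify); in each, the second column is
    randomly permuted across sequences and the pair is re-scored, and the
    sample variance of these shuffled scores is returned.
    """
    values = scores.scores()
    if values.size < 2:
        raise ValueError("need at least two pair scores")
    if nu < 2:
        raise ValueError("nu must be at least 2")
    mean = float(values.mean())

    lo, hi = subinterval
    pairs = scores.pairs()
    candidates = [p for p, s in zip(pairs, values) if lo <= s <= hi]
    if not candidates:
        logger.warning(
            "no pair score in subinterval [%g, %g]; sampling from all pairs", lo, hi
        )
        candidates = pairs
    rng = np.random.default_rng(seed)
    if len(candidates) > nu:
        chosen = [candidates[k] for k in rng.choice(len(candidates), nu, replace=False)]
    else:
        chosen = list(candidates)
        if len(candidates) < nu:
            logger.info(
                "only %d pairs available for variance estimation (nu=%d)",
                len(candidates),
                nu,
            )

    codes = msa.codes()
    kwargs = {}
    if scores.metric_name == "UD":
        kwargs = {"metric": "UD", "dcm": dcm, "alpha": alpha}
    shuffled = np.empty(len(chosen))
    for k, (i, j) in enumerate(chosen):
        permuted = codes[rng.permutation(codes.shape[0]), j]
        shuffled[k] = score_from_codes(codes[:, i], permuted, **kwargs)
    variance = float(np.var(shuffled, ddof=1))
    return mean, variance


def fit_beta_moments(mean: float, variance: float, metric_name: str = "") -> BetaNull:
    """Method-of-moments beta fit: k = m(1-m)/v - 1, a = m*k, b = (1-m)*k."""
    if not (0 < mean < 1):
        raise ValueError(f"mean {mean:.4g} outside (0, 1)")
    if variance <= 0:
        raise ValueError("variance must be positive")
    if variance >= mean * (1 - mean):
        raise ValueError(
            f"infeasible moments: variance {variance:.4g} >= "
            f"mean*(1-mean) = {mean * (1 - mean):.4g}"
        )
    k = mean * (1 - mean) / variance - 1
    return BetaNull(
        a=mean * k, b=(1 - mean) * k, mean=mean, variance=variance,
        metric_name=metric_name,
    )


def p_values(scores: PairScoreTable, null: BetaNull) -> np.ndarray:
    """Upper-tail p-values 1 - F0(score), antitone in the score."""
    return np.asarray(null.sf(scores.scores()), dtype=float)


def estimate_gamma(
    pvalues, lambda1: float = 0.25, lambda2: float = 0.70
) -> float:
    """Estimated null fraction: #{p in [l1, l2]} / (mu * (l2 - l1)),
    clipped to [1/mu, 1]."""
    if not (0 <= lambda1 < lambda2 <= 1):
        raise ValueError("require 0 <= lambda1 < lambda2 <= 1")
    p = np.asarray(pvalues, dtype=float)
    mu = p.size
    if mu == 0:
        raise ValueError("no p-values")
    count = int(((p >= lambda1) & (p <= lambda2)).sum())
    gamma = count / (mu * (lambda2 - lambda1))
    clipped = min(1.0, max(1.0 / mu, gamma))
    if clipped != gamma:
        logger.info("gamma estimate %.4g clipped to %.4g", gamma, clipped)
    return clipped


def fdr_threshold(
    pvalues, gamma_hat: float, target_fdr: float, lambda1: float = 0.25
):
    """Largest observed p-value t <= lambda1 with estimated FDR <= target.

    Returns ``(tau, fdr_hat_at_tau)``; ``(0.0, 0.0)`` when no candidate
    qualifies (no significant pairs).
    """
    if not (0 < target_fdr < 1):
        raise ValueError("target FDR must lie in (0, 1)")
    p = np.sort(np.asarray(pvalues, dtype=float))
    mu = p.size
    candidates = np.unique(p[p <= lambda1])
    if candidates.size == 0:
        return 0.0, 0.0
    counts = np.searchsorted(p, candidates, side="right")
    fdr_hat = gamma_hat * mu * candidates / counts
    ok = np.where(fdr_hat <= target_fdr)[0]
    if ok.size == 0:
        return 0.0, 0.0
    best = ok[-1]
    return float(candidates[best]), float(fdr_hat[best])


def significant_pairs(scores: PairScoreTable, pvalues, tau: float) -> set:
    """The pairs with p <= tau; empty when tau is 0 (nothing significant)."""
    if tau <= 0:
        return set()
    p = np.asarray(pvalues, dtype=float)
    return {pair for pair, pv in zip(scores.pairs(), p) if pv <= tau}


def connectivity_degrees(sig_pairs, sites) -> dict:
    """Per-site count of significant pairs containing the site."""
    degrees = {s: 0 for s in sites}
    for i, j in sig_pairs:
        degrees[i] += 1
        degrees[j] += 1
    return degrees


def significant_sites(connectivity: dict, percentile: float = 90, strict: bool = False):
    """Sites whose degree reaches the nearest-rank percentile of nonzero
    degrees.

    Returns ``(degree_threshold, site_set)``; threshold is ``None`` (and the
    set empty) when no site has a nonzero degree.  With ``strict`` the
    comparison is ``>`` instead of ``>=``.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0, 100)")
    nonzero = sorted(d for d in connectivity.values() if d >= 1)
    if not nonzero:
        return None, set()
    rank = max(1, math.ceil(percentile / 100 * len(nonzero)))
    threshold = nonzero[rank - 1]
    if strict:
        sites = {s for s, d in connectivity.items() if d > threshold}
    else:
        sites = {s for s, d in connectivity.items() if d >= threshold}
    return threshold, sites


def analyze(
    msa: Alignment,
    scores: PairScoreTable,
    target_fdr: float = 0.01,
    lambda1: float = 0.25,
    lambda2: float = 0.70,
    nu: int = 1000,
    subinterval=(0.2, 0.8),
    percentile: float = 90,
    strict_percentile: bool = False,
    seed: int = 0,
    dcm=None,
    alpha: float = 1.0,
) -> SignificanceResult:
    """Run the full significance scan for one metric on one MSA."""
    effective_nu = min(nu, len(scores.entries))
    mean, variance = estimate_null_moments(
        msa, scores, nu=max(2, effective_nu), subinterval=subinterval,
        seed=seed, dcm=dcm, alpha=alpha,
    )
    null = fit_beta_moments(mean, variance, metric_name=scores.metric_name)
    pvals = p_values(scores, null)
    gamma_hat = estimate_gamma(pvals, lambda1, lambda2)
    tau, fdr_at_tau = fdr_threshold(pvals, gamma_hat, target_fdr, lambda1)
    sig = significant_pairs(scores, pvals, tau)
    connectivity = connectivity_degrees(sig, range(msa.n_cols))
    threshold, sites = significant_sites(
        connectivity, percentile=percentile, strict=strict_percentile
    )
    return SignificanceResult(
        metric_name=scores.metric_name,
        pairs=scores.pairs(),
        scores=scores.scores(),
        pvalues=pvals,
        null=null,
        gamma_hat=gamma_hat,
        tau=tau,
        fdr_hat_at_tau=fdr_at_tau,
        significant_pairs=sig,
        connectivity=connectivity,
        degree_threshold=threshold,
        significant_sites=sites,
        lambda1=lambda1,
        lambda2=lambda2,
        nu=effective_nu,
        seed=seed,
        n_columns=msa.n_cols,
    )


def cmf_sites(u_result: SignificanceResult, ud_result: SignificanceResult) -> dict:
    """Union of the per-metric significant sites with annotation.

    Returns ``{site: {"u_significant", "ud_significant", "both",
    "degree_u", "degree_ud"}}`` keyed by filtered-column index.
    """
    if u_result.n_columns != ud_result.n_columns:
        raise ValueError("results come from different alignments")
    out = {}
    for site in u_result.significant_sites | ud_result.significant_sites:
        in_u = site in u_result.significant_sites
        in_ud = site in ud_result.significant_sites
        out[site] = {
            "u_significant": in_u,
            "ud_significant": in_ud,
            "both": in_u and in_ud,
            "degree_u": u_result.connectivity.get(site, 0),
            "degree_ud": ud_result.connectivity.get(site, 0),
        }
    return out
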